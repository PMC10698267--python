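"""Configuration-driven end-to-end analysis runner.

A single YAML config describes either real input files (genotype CSV +
popmap TSV) or a synthetic-simulation block, plus population roles and
per-stage settings.  ``run_pipeline`` executes the hybrid-zone analysis in
the canonical order

    diversity -> temporal pooling -> pairwise F_ST -> PCA + Tracy-Widom
    -> admixture + Evanno Delta-K -> hybrid classification -> D-statistics

writing every result table as TSV plus a run log (seeds, stage decisions)
and a plain-text summary.  The pipeline is a pure function of
(inputs, config, seeds): re-runs with the same config are reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify, estimate_pool_frequencies, power_simulation
from .dstat import dstat_panel_sweep
from .panel import GenotypePanel, read_panel, write_panel
from .popgen import compare_diversity, diversity_table, pairwise_fst, temporal_pooling
from .simulate import (
    LineageFrequencies,
    SimConfig,
    apply_missingness,
    concat_panels,
    make_lineage_frequencies,
    simulate_population,
)
from .structure import (
    admixture_summary,
    align_replicates,
    evanno_delta_k,
    pca,
    q_matrix_frame,
    run_admixture_replicates,
)


class PipelineConfigError(ValueError):
    """Invalid or contradictory pipeline configuration."""


@dataclass
class PipelineBundle:
    outdir: Path
    panel: GenotypePanel
    tables: dict[str, pd.DataFrame]
    summary: str


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config must be a YAML mapping")
    return cfg


def _build_synthetic_panel(block: dict, seed: int) -> tuple[GenotypePanel, LineageFrequencies]:
    sim_cfg = SimConfig(
        n_loci=int(block.get("n_loci", 96)),
        diagnosticity=float(block.get("diagnosticity", 0.9)),
        missing_rate=float(block.get("missing_rate", 0.0)),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    freqs = make_lineage_frequencies(sim_cfg, rng)
    pops = block.get("populations")
    if not pops:
        raise PipelineConfigError("synthetic block needs a 'populations' list")
    panels = []
    for spec in pops:
        panels.append(
            simulate_population(
                freqs,
                source=spec["source"],
                n=int(spec["n"]),
                rng=rng,
                label=spec["name"],
                year=spec.get("year"),
            )
        )
    panel = concat_panels(panels)
    if sim_cfg.missing_rate > 0:
        panel = apply_missingness(panel, sim_cfg.missing_rate, rng)
    return panel, freqs


def run_pipeline(config: dict, outdir: str | os.PathLike) -> PipelineBundle:
    """Execute every analysis stage and write the report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: list[str] = [f"hybridpanel {__version__}", f"seed={seed}"]
    tables: dict[str, pd.DataFrame] = {}

    has_input = "input" in config
    has_synth = "synthetic" in config
    if has_input == has_synth:
        raise PipelineConfigError("config must contain exactly one of 'input' or 'synthetic'")

    stage = "load"
    try:
        if has_input:
            panel = read_panel(config["input"]["genotypes"], config["input"]["popmap"])
            log.append(f"loaded {panel.n_samples} samples x {panel.n_loci} loci")
        else:
            panel, _freqs = _build_synthetic_panel(config["synthetic"], seed)
            write_panel(panel, outdir / "synthetic_genotypes.csv", outdir / "synthetic_popmap.tsv")
            log.append(f"simulated {panel.n_samples} samples x {panel.n_loci} loci")

        roles = config.get("roles", {})
        north = roles.get("parental_north")
        south = roles.get("parental_south")
        outgroup = roles.get("outgroup")
        for name, pop in (("parental_north", north), ("parental_south", south), ("outgroup", outgroup)):
            if pop is not None and pop not in panel.populations:
                raise PipelineConfigError(f"role {name} refers to unknown population {pop!r}")
        analysis_pops = [p for p in panel.populations if p != outgroup]

        stage = "diversity"
        n_perm = int(config.get("n_permutations", 1000))
        tables["diversity"] = diversity_table(panel, analysis_pops)
        if len(analysis_pops) >= 2:
            tables["diversity_anova"] = compare_diversity(panel, analysis_pops)
        log.append("diversity: done")

        stage = "temporal_pooling"
        alpha = float(config.get("pooling_alpha", 0.05))
        panel, pooling_report = temporal_pooling(panel, alpha=alpha, n_perm=n_perm, seed=seed + 1)
        tables["temporal_pooling"] = pooling_report
        analysis_pops = [p for p in panel.populations if p != outgroup]
        for _, row in pooling_report.iterrows():
            log.append(
                f"temporal pooling {row['location']}: theta={row['theta']}, p={row['p']}, pooled={row['pooled']}"
            )

        stage = "fst"
        tables["pairwise_fst"] = pairwise_fst(panel, analysis_pops, n_perm=n_perm, seed=seed + 2)
        log.append("pairwise F_ST: done")

        stage = "pca"
        pca_res = pca(panel, analysis_pops)
        coords = pd.DataFrame(
            pca_res.coordinates[:, : min(10, pca_res.coordinates.shape[1])],
            columns=[f"PC{i + 1}" for i in range(min(10, pca_res.coordinates.shape[1]))],
        )
        coords.insert(0, "sample", pca_res.sample_ids)
        pops_of = dict(zip(panel.sample_ids, panel.pop_labels))
        coords.insert(1, "population", [pops_of[s] for s in pca_res.sample_ids])
        tables["pca_coordinates"] = coords
        tables["pca_eigen"] = pd.DataFrame(
            {
                "axis": np.arange(1, pca_res.eigenvalues.size + 1),
                "eigenvalue": pca_res.eigenvalues,
                "variance_explained_pct": 100 * pca_res.variance_explained,
                "tw_p": pca_res.tw_pvalues,
            }
        )
        log.append(
            f"PCA: {pca_res.n_significant} significant axes; "
            f"PC1 {100 * pca_res.variance_explained[0]:.1f}% of variance"
        )

        stage = "admixture"
        k_max = int(config.get("k_max", 4))
        n_rep = int(config.get("admixture_replicates", 10))
        runs = run_admixture_replicates(panel.subset_samples(
            np.array([p != outgroup for p in panel.pop_labels])
        ), list(range(1, k_max + 1)), n_replicates=n_rep, seed=seed + 3)
        lls = {k: [r.log_likelihood for r in results] for k, results in runs.items()}
        dk = evanno_delta_k(lls)
        tables["evanno"] = dk.table
        best_k = dk.chosen_k
        best = align_replicates(sorted(runs[best_k], key=lambda r: -r.log_likelihood))
        q_labels = [p for p in panel.pop_labels if p != outgroup]
        tables["q_matrix"] = q_matrix_frame(best[0], q_labels)
        tables["admixture_summary"] = admixture_summary(
            best[0], q_labels, threshold=float(config.get("admixture_threshold", 0.10))
        )
        log.append(f"admixture: Evanno Delta-K chose K={best_k}")

        stage = "classification"
        if north and south:
            est = estimate_pool_frequencies(
                panel, north, south, pseudocount=float(config.get("pseudocount", 0.5))
            )
            query_pops = roles.get("query") or [
                p for p in analysis_pops if p not in (north, south)
            ]
            if isinstance(query_pops, str):
                query_pops = [query_pops]
            mask = np.array([p in query_pops for p in panel.pop_labels])
            if mask.any():
                sub = panel.subset_samples(mask)
                res = classify(sub, est)
                tables["classification"] = res.to_frame(sub.pop_labels)
                log.append(f"classified {mask.sum()} query individuals")
            else:
                log.append("classification: no query individuals")
        else:
            log.append("classification skipped: parental roles not set")

        stage = "dstat"
        if north and south and outgroup:
            trios = config.get("dstat_pairs")
            if trios is None:
                northern = [p for p in analysis_pops if p not in (south,)]
                trios = [(a, b) for i, a in enumerate(northern) for b in northern[i + 1:]]
            trios = [tuple(t) for t in trios]
            if trios:
                tables["dstat"] = dstat_panel_sweep(panel, p3=south, outgroup=outgroup, pairs=trios)
                log.append(f"D-statistics: {len(trios)} trios")
        else:
            log.append("D-statistics skipped: needs parental_south and outgroup roles")
    except PipelineConfigError:
        raise
    except Exception as exc:  # pragma: no cover - stage-labelled re-raise
        _flush(outdir, tables, log + [f"FAILED at stage {stage}: {exc}"])
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = _flush(outdir, tables, log)
    return PipelineBundle(outdir=outdir, panel=panel, tables=tables, summary=summary)


def _flush(outdir: Path, tables: dict[str, pd.DataFrame], log: list[str]) -> str:
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=name == "pairwise_fst",
                  float_format="%.6g")
    summary = "\n".join(log) + "\n"
    (outdir / "run_log.txt").write_text(summary)
    return summary


def run_power(config: dict, outdir: str | os.PathLike) -> None:
    """Marker-power study from a config 'power' block."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block = config.get("power", {})
    seed = int(config.get("seed", 0))
    sim_cfg = SimConfig(
        n_loci=int(block.get("n_loci", 96)),
        diagnosticity=float(block.get("diagnosticity", 1.0)),
        seed=seed,
    )
    freqs = make_lineage_frequencies(sim_cfg)
    report = power_simulation(
        freqs,
        n_per_category=int(block.get("n_per_category", 10_000)),
        seed=seed,
        baseline_n=int(block.get("baseline_n", 30)),
        pseudocount=float(block.get("pseudocount", 0.5)),
    )
    report.confusion.to_csv(outdir / "power_confusion.tsv", sep="\t")
    report.summary.to_csv(outdir / "power_summary.tsv", sep="\t", index=False)
    meta = {"seed": seed, "n_per_category": report.n_per_category, "n_total": report.n_total}
    (outdir / "power_meta.json").write_text(json.dumps(meta, indent=2))


def make_figures(bundle_dir: str | os.PathLike, outdir: str | os.PathLike | None = None) -> list[Path]:
    """Render basic figures (PCA scatter, ancestry bars, class composition)
    deterministically from the TSVs in a pipeline bundle directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bundle_dir = Path(bundle_dir)
    outdir = Path(outdir) if outdir else bundle_dir
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pca_path = bundle_dir / "pca_coordinates.tsv"
    if pca_path.exists():
        df = pd.read_csv(pca_path, sep="\t")
        if df.empty:
            raise ValueError("empty PCA coordinate table")
        fig, ax = plt.subplots(figsize=(5, 4))
        for pop, grp in df.groupby("population"):
            ax.scatter(grp["PC1"], grp.get("PC2", 0), label=pop, s=18)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / "pca_scatter.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    q_path = bundle_dir / "q_matrix.tsv"
    if q_path.exists():
        df = pd.read_csv(q_path, sep="\t")
        if df.empty:
            raise ValueError("empty Q matrix")
        qcols = [c for c in df.columns if c.startswith("q_")]
        df = df.sort_values(["population", qcols[0]]).reset_index(drop=True)
        fig, ax = plt.subplots(figsize=(max(4, len(df) * 0.08), 2.5))
        bottom = np.zeros(len(df))
        for c in qcols:
            ax.bar(np.arange(len(df)), df[c], bottom=bottom, width=1.0)
            bottom += df[c].to_numpy()
        ax.set_xlim(-0.5, len(df) - 0.5)
        ax.set_ylabel("ancestry q")
        fig.tight_layout()
        path = outdir / "ancestry_bars.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    cls_path = bundle_dir / "classification.tsv"
    if cls_path.exists():
        df = pd.read_csv(cls_path, sep="\t")
        comp = df.groupby(["population", "MAP"]).size().unstack(fill_value=0)
        comp = comp.div(comp.sum(axis=1), axis=0)
        fig, ax = plt.subplots(figsize=(5, 3))
        comp.plot(kind="bar", stacked=True, ax=ax, legend=True)
        ax.set_ylabel("class fraction")
        ax.legend(fontsize=6)
        fig.tight_layout()
        path = outdir / "class_composition.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if not written:
        raise FileNotFoundError(f"no renderable tables found in {bundle_dir}")
    return written
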