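"""Genotype panel data model and I/O.

A :class:`GenotypePanel` holds an individuals x loci matrix of biallelic
genotype codes counting copies of the designated "southern"-lineage allele
(0 = homozygous northern, 1 = heterozygous, 2 = homozygous southern,
``MISSING`` = no call), together with per-sample population labels and an
optional collection year.  All statistics downstream use pairwise-complete
per-locus deletion of missing calls; individuals are never dropped entirely.

File formats
------------
* genotype CSV: header row of locus ids, first column sample id, cells in
  ``{0,1,2,NA}`` (comma separated, ``NA`` = missing);
* population map TSV: 2-3 columns ``sample<TAB>population[<TAB>year]``;
* VCF 4.x (biallelic SNPs, GT field) via cyvcf2, as a convenience reader.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel genotype code for a missing call.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class PanelFormatError(ValueError):
    """A genotype or popmap file does not conform to the expected dialect."""


class PanelValidationError(ValueError):
    """Panel contents violate a structural invariant."""


@dataclass
class PopulationMap:
    """Population membership plus optional analysis role tags.

    Roles mark at most one population each as ``parental_north``,
    ``parental_south`` or ``outgroup``; any number may be tagged ``query``.
    """

    members: dict[str, list[str]]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for pop, samples in self.members.items():
            for s in samples:
                if s in seen:
                    raise PanelValidationError(
                        f"sample {s!r} appears in both {seen[s]!r} and {pop!r}"
                    )
                seen[s] = pop
        single = ("parental_north", "parental_south", "outgroup")
        for role in single:
            tagged = [p for p, r in self.roles.items() if r == role]
            if len(tagged) > 1:
                raise PanelValidationError(f"role {role!r} tagged on multiple populations: {tagged}")

    def population_for_role(self, role: str) -> str | None:
        for pop, r in self.roles.items():
            if r == role:
                return pop
        return None


@dataclass
class GenotypePanel:
    """Individuals x biallelic-loci genotype matrix with population labels."""

    sample_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray  # (n_samples, n_loci) int8, codes {0,1,2,MISSING}
    pop_labels: list[str]
    year: list[int | None] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise PanelValidationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        bad = set(np.unique(self.genotypes)) - _VALID_CODES
        if bad:
            raise PanelValidationError(f"invalid genotype codes {sorted(bad)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = [s for s in set(self.sample_ids) if self.sample_ids.count(s) > 1]
            raise PanelValidationError(f"duplicate sample ids: {dupes}")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise PanelValidationError("duplicate locus ids")
        if len(self.pop_labels) != len(self.sample_ids):
            raise PanelValidationError("every sample needs a population label")
        if self.year is not None and len(self.year) != len(self.sample_ids):
            raise PanelValidationError("year vector length mismatch")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.pop_labels:
            if p not in seen:
                seen.append(p)
        return seen

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def population_mask(self, population: str) -> np.ndarray:
        if population not in self.pop_labels:
            raise KeyError(f"unknown population {population!r}")
        return np.array([p == population for p in self.pop_labels])

    def population_genotypes(self, population: str) -> np.ndarray:
        """Genotype sub-matrix for one population (rows = its samples)."""
        return self.genotypes[self.population_mask(population)]

    def subset_samples(self, mask: np.ndarray) -> "GenotypePanel":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in idx],
            locus_ids=list(self.locus_ids),
            genotypes=self.genotypes[idx],
            pop_labels=[self.pop_labels[i] for i in idx],
            year=None if self.year is None else [self.year[i] for i in idx],
        )

    def with_pop_labels(self, labels: list[str]) -> "GenotypePanel":
        return replace(self, pop_labels=list(labels))

    # -- allele counting -------------------------------------------------

    def allele_counts(self, population: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus count of the southern (B) allele and of called gene copies.

        Returns ``(count_B, called_copies)``; ``called_copies`` is twice the
        number of called genotypes, so it is always even.
        """
        g = self.genotypes if population is None else self.population_genotypes(population)
        called = g != MISSING
        count_b = np.where(called, g, 0).sum(axis=0)
        copies = 2 * called.sum(axis=0)
        return count_b.astype(np.int64), copies.astype(np.int64)


def allele_frequencies(panel: GenotypePanel, population: str | None = None) -> np.ndarray:
    """Per-locus frequency of allele B in one population (NaN where no calls)."""
    count_b, copies = panel.allele_counts(population)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(copies > 0, count_b / np.maximum(copies, 1), np.nan)
    return freq


def orient_to_south(panel: GenotypePanel, south_population: str) -> tuple[GenotypePanel, list[str]]:
    """Flip per-locus allele coding so code 2 is the southern-majority allele.

    Loci where the southern reference population has coded-allele frequency
    below 0.5 are recoded 0<->2.  Returns the re-oriented panel and the list
    of flipped locus ids (frequency exactly 0.5 or all-missing loci are left
    as loaded; the orientation there is arbitrary).
    """
    freq = allele_frequencies(panel, south_population)
    flip = np.nan_to_num(freq, nan=1.0) < 0.5
    g = panel.genotypes.copy()
    cols = np.flatnonzero(flip)
    sub = g[:, cols]
    sub[sub != MISSING] = 2 - sub[sub != MISSING]
    g[:, cols] = sub
    flipped = [panel.locus_ids[i] for i in cols]
    return replace(panel, genotypes=g), flipped


# -- I/O ------------------------------------------------------------------


def read_popmap(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] not in (2, 3):
        raise PanelFormatError(f"popmap must have 2-3 tab-separated columns, got {df.shape[1]}")
    df.columns = ["sample", "population", "year"][: df.shape[1]]
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise PanelValidationError(f"duplicate sample ids in popmap: {dupes}")
    return df


def read_panel(genotype_path: str | os.PathLike, popmap_path: str | os.PathLike) -> GenotypePanel:
    """Read a genotype CSV plus popmap TSV into a validated panel."""
    df = pd.read_csv(genotype_path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise PanelFormatError("genotype CSV needs a sample column and >=1 locus column")
    sample_col = df.columns[0]
    sample_ids = df[sample_col].tolist()
    locus_ids = [str(c) for c in df.columns[1:]]
    mat = np.empty((len(sample_ids), len(locus_ids)), dtype=np.int8)
    for j, locus in enumerate(locus_ids):
        col = df[locus].str.strip()
        for i, cell in enumerate(col):
            if cell == "NA":
                mat[i, j] = MISSING
            elif cell in ("0", "1", "2"):
                mat[i, j] = int(cell)
            else:
                raise PanelFormatError(
                    f"malformed genotype {cell!r} at sample {sample_ids[i]!r}, locus {locus!r}"
                )
    popmap = read_popmap(popmap_path)
    pop_of = dict(zip(popmap["sample"], popmap["population"]))
    missing_samples = [s for s in sample_ids if s not in pop_of]
    if missing_samples:
        raise PanelValidationError(f"samples absent from popmap: {missing_samples}")
    year = None
    if "year" in popmap.columns:
        year_of = dict(zip(popmap["sample"], popmap["year"]))
        year = [int(y) if y not in ("", "NA", None) else None for y in (year_of[s] for s in sample_ids)]
    return GenotypePanel(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        genotypes=mat,
        pop_labels=[pop_of[s] for s in sample_ids],
        year=year,
    )


def write_panel(panel: GenotypePanel, genotype_path: str | os.PathLike, popmap_path: str | os.PathLike) -> None:
    """Write the panel back out in the package CSV + popmap TSV dialect."""
    cells = panel.genotypes.astype(object)
    cells[panel.genotypes == MISSING] = "NA"
    df = pd.DataFrame(cells, columns=panel.locus_ids)
    df.insert(0, "sample", panel.sample_ids)
    df.to_csv(genotype_path, index=False)
    rows: dict[str, list] = {"sample": panel.sample_ids, "population": panel.pop_labels}
    if panel.year is not None:
        rows["year"] = ["NA" if y is None else y for y in panel.year]
    pd.DataFrame(rows).to_csv(popmap_path, sep="\t", index=False, header=False)


def read_vcf(path: str | os.PathLike, popmap_path: str | os.PathLike) -> GenotypePanel:
    """Read biallelic SNP genotypes from a VCF (GT field) plus a popmap.

    GT 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> MISSING; phase is ignored.
    Multiallelic or non-SNP records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    sample_ids = list(vcf.samples)
    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise PanelFormatError(
                f"record {rec.CHROM}:{rec.POS} is not a biallelic SNP (REF={rec.REF}, ALT={rec.ALT})"
            )
        locus_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        columns.append(col.astype(np.int8))
    if not columns:
        raise PanelFormatError(f"no records in VCF {path}")
    mat = np.stack(columns, axis=1)
    popmap = read_popmap(popmap_path)
    pop_of = dict(zip(popmap["sample"], popmap["population"]))
    absent = [s for s in sample_ids if s not in pop_of]
    if absent:
        raise PanelValidationError(f"samples absent from popmap: {absent}")
    return GenotypePanel(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        genotypes=mat,
        pop_labels=[pop_of[s] for s in sample_ids],
    )


def panel_to_frame(panel: GenotypePanel) -> pd.DataFrame:
    """Genotypes as a DataFrame (NaN for missing), indexed by sample id."""
    g = panel.genotypes.astype(float)
    g[panel.genotypes == MISSING] = np.nan
    return pd.DataFrame(g, index=panel.sample_ids, columns=panel.locus_ids)
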