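"""Diversity and differentiation statistics.

Observed/expected heterozygosity, rarefied allelic richness, one-way ANOVA
comparisons across populations, pairwise Weir-Cockerham theta (F_ST) with a
permutation test, and the temporal-pooling rule (pool two temporal samples
from one location unless their F_ST is significant).

Missing genotypes are handled by pairwise-complete per-locus deletion
throughout; individuals are never dropped entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .panel import MISSING, GenotypePanel


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def observed_heterozygosity(panel: GenotypePanel, population: str) -> tuple[float, np.ndarray]:
    """Mean and per-locus Ho (fraction of called genotypes that are heterozygous).

    All-missing loci are excluded from the mean with a warning.
    """
    g = panel.population_genotypes(population)
    if g.shape[0] == 0:
        raise ValueError(f"population {population!r} is empty")
    called = g != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        ho = np.where(n_called > 0, (g == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    if np.any(n_called == 0):
        warnings.warn(f"{int((n_called == 0).sum())} all-missing loci excluded from Ho")
    return float(np.nanmean(ho)), ho


def expected_heterozygosity(panel: GenotypePanel, population: str) -> tuple[float, np.ndarray]:
    """Unbiased expected heterozygosity, averaged over loci.

    Per locus: He = (2n / (2n - 1)) * (1 - p^2 - q^2) with n called diploids.
    """
    g = panel.population_genotypes(population)
    if g.shape[0] == 0:
        raise ValueError(f"population {population!r} is empty")
    called = g != MISSING
    n = called.sum(axis=0)
    count_b = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = count_b / np.maximum(2 * n, 1)
        he = np.where(n > 0, (2 * n) / np.maximum(2 * n - 1, 1) * (1 - p**2 - (1 - p) ** 2), np.nan)
    he = np.where(n > 0, he, np.nan)
    return float(np.nanmean(he)), he


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(
    panel: GenotypePanel, population: str, rarefaction_copies: int | None = None
) -> tuple[float, np.ndarray]:
    """Rarefied allelic richness per locus, averaged.

    AR_l = sum over alleles of ``1 - C(N - N_i, g) / C(N, g)`` where N is the
    number of called gene copies at locus l, N_i the copies of allele i, and
    g the rarefaction size (default: the minimum per-locus called copies in
    this population).  Loci with N < g are skipped with a warning.  For a
    biallelic locus AR lies in [1, 2].
    """
    count_b, copies = panel.allele_counts(population)
    if copies.max(initial=0) == 0:
        raise ValueError(f"population {population!r} has no called genotypes")
    g = rarefaction_copies
    if g is None:
        g = int(copies[copies > 0].min())
    if g < 1:
        raise ValueError("rarefaction size must be >= 1")
    ar = np.full(copies.shape, np.nan)
    usable = copies >= g
    if not np.all(usable | (copies == 0)):
        warnings.warn(f"{int((~usable & (copies > 0)).sum())} loci with fewer than g={g} copies skipped")
    n = copies[usable].astype(float)
    nb = count_b[usable].astype(float)
    na = n - nb
    log_cn = _log_comb(n, g)
    terms = np.zeros(n.shape)
    for ni in (na, nb):
        with np.errstate(invalid="ignore"):
            miss_prob = np.where(n - ni >= g, np.exp(_log_comb(n - ni, g) - log_cn), 0.0)
        terms += 1.0 - miss_prob
    ar[usable] = terms
    return float(np.nanmean(ar)), ar


def diversity_table(panel: GenotypePanel, populations: list[str] | None = None,
                    rarefaction_copies: int | None = None) -> pd.DataFrame:
    """Per-population Ho, He, AR and sample size, one row per population."""
    pops = populations or panel.populations
    if rarefaction_copies is None:
        # standardize AR to the smallest per-locus called copies across pops
        rarefaction_copies = min(
            int(c[c > 0].min()) for c in (panel.allele_counts(p)[1] for p in pops)
        )
    rows = []
    for pop in pops:
        ho, _ = observed_heterozygosity(panel, pop)
        he, _ = expected_heterozygosity(panel, pop)
        ar, _ = allelic_richness(panel, pop, rarefaction_copies)
        rows.append(
            {"population": pop, "n": int(panel.population_mask(pop).sum()),
             "Ho": ho, "He": he, "AR": ar}
        )
    return pd.DataFrame(rows)


def compare_diversity(
    panel: GenotypePanel, populations: list[str] | None = None,
    rarefaction_copies: int | None = None,
) -> pd.DataFrame:
    """One-way ANOVA of per-locus diversity values grouped by population.

    Returns F and p for each of Ho, He and AR.
    """
    pops = populations or panel.populations
    if len(pops) < 2:
        raise ValueError("ANOVA needs at least two populations")
    if rarefaction_copies is None:
        rarefaction_copies = min(
            int(c[c > 0].min()) for c in (panel.allele_counts(p)[1] for p in pops)
        )
    per_locus = {
        "Ho": [observed_heterozygosity(panel, p)[1] for p in pops],
        "He": [expected_heterozygosity(panel, p)[1] for p in pops],
        "AR": [allelic_richness(panel, p, rarefaction_copies)[1] for p in pops],
    }
    rows = []
    for stat_name, groups in per_locus.items():
        clean = [g[~np.isnan(g)] for g in groups]
        f, p = stats.f_oneway(*clean)
        rows.append({"statistic": stat_name, "F": float(f), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    theta: float
    per_locus: pd.DataFrame  # columns locus, a, b, c
    n_loci_used: int


def _wc_components(g_a: np.ndarray, g_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, b, c) for two samples.

    Returns (a, b, c, usable) over all loci; loci with <2 called individuals
    in either sample or monomorphic across both are marked unusable.
    """
    r = 2
    comps = []
    for g in (g_a, g_b):
        called = g != MISSING
        n_i = called.sum(axis=0).astype(float)  # called diploids
        count_b = np.where(called, g, 0).sum(axis=0).astype(float)
        het = ((g == 1) & called).sum(axis=0).astype(float)
        comps.append((n_i, count_b, het))
    n1, cb1, het1 = comps[0]
    n2, cb2, het2 = comps[1]
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = cb1 / (2 * n1)
        p2 = cb2 / (2 * n2)
        h1 = het1 / n1
        h2 = het2 / n2
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
    monomorphic = (p_bar == 0) | (p_bar == 1)
    usable &= ~monomorphic
    return a, b, c, usable


def weir_cockerham_fst(panel: GenotypePanel, pop_a: str, pop_b: str) -> FstResult:
    """Two-population Weir-Cockerham theta, multilocus ratio of sums.

    Loci monomorphic across both populations, or with fewer than two called
    individuals in either, are excluded.  Theta may be negative; it is
    reported as computed.
    """
    g_a = panel.population_genotypes(pop_a)
    g_b = panel.population_genotypes(pop_b)
    a, b, c, usable = _wc_components(g_a, g_b)
    if not usable.any():
        raise ValueError(f"no shared informative loci between {pop_a!r} and {pop_b!r}")
    denom = (a + b + c)[usable].sum()
    theta = float(a[usable].sum() / denom)
    per_locus = pd.DataFrame(
        {
            "locus": [panel.locus_ids[i] for i in np.flatnonzero(usable)],
            "a": a[usable],
            "b": b[usable],
            "c": c[usable],
        }
    )
    return FstResult(theta=theta, per_locus=per_locus, n_loci_used=int(usable.sum()))


def _theta_from_matrices(g_a: np.ndarray, g_b: np.ndarray) -> float:
    a, b, c, usable = _wc_components(g_a, g_b)
    if not usable.any():
        return np.nan
    denom = (a + b + c)[usable].sum()
    if denom == 0:
        return np.nan
    return float(a[usable].sum() / denom)


def fst_permutation_test(
    panel: GenotypePanel, pop_a: str, pop_b: str, n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation p-value for theta, permuting individuals between the pair.

    p = (1 + #{permuted theta >= observed}) / (n_perm + 1).
    Returns (observed theta, p).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g_a = panel.population_genotypes(pop_a)
    g_b = panel.population_genotypes(pop_b)
    observed = _theta_from_matrices(g_a, g_b)
    pooled = np.vstack([g_a, g_b])
    n_a = g_a.shape[0]
    n_tot = pooled.shape[0]
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(n_tot)
        t = _theta_from_matrices(pooled[idx[:n_a]], pooled[idx[n_a:]])
        if not np.isnan(t) and t >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return observed, float(p)


def pairwise_fst(
    panel: GenotypePanel, populations: list[str] | None = None,
    n_perm: int = 10_000, seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """All pairwise theta (lower triangle) and permutation p (upper triangle)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pops = populations or panel.populations
    out = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for j in range(i + 1, len(pops)):
            pb = pops[j]
            theta, p = fst_permutation_test(panel, pa, pb, n_perm=n_perm, seed=rng)
            out.loc[pops[j], pa] = theta  # lower triangle
            out.loc[pa, pops[j]] = p      # upper triangle
    return out


# ---------------------------------------------------------------------------
# temporal pooling
# ---------------------------------------------------------------------------


def temporal_pooling(
    panel: GenotypePanel, alpha: float = 0.05, n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Pool temporal samples within locations unless F_ST between years is significant.

    For every location (population label) sampled in exactly two years,
    compute theta and its permutation p between the year groups; if
    p < alpha the location is split into ``location_year`` populations,
    otherwise the samples stay pooled under the location label.  Locations
    with a single year pass through.  Returns the (possibly relabeled) panel
    and a per-location report.
    """
    if panel.year is None:
        return panel, pd.DataFrame(columns=["location", "years", "theta", "p", "pooled"])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(panel.pop_labels)
    rows = []
    for loc in panel.populations:
        idx = np.flatnonzero(panel.population_mask(loc))
        years = sorted({panel.year[i] for i in idx if panel.year[i] is not None})
        if len(years) < 2:
            rows.append({"location": loc, "years": years, "theta": np.nan, "p": np.nan, "pooled": True})
            continue
        year_labels = [f"{loc}_{panel.year[i]}" for i in idx]
        sub = panel.subset_samples(panel.population_mask(loc)).with_pop_labels(year_labels)
        ya, yb = f"{loc}_{years[0]}", f"{loc}_{years[1]}"
        theta, p = fst_permutation_test(sub, ya, yb, n_perm=n_perm, seed=rng)
        pooled = p >= alpha
        if not pooled:
            for i in idx:
                labels[i] = f"{loc}_{panel.year[i]}"
        rows.append({"location": loc, "years": years, "theta": theta, "p": p, "pooled": pooled})
    return panel.with_pop_labels(labels), pd.DataFrame(rows)
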