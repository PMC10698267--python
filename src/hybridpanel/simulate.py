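"""Synthetic two-lineage panels and Mendelian hybrid genotypes.

The generator emulates the statistical structure of a diagnostic SNP array
typed on a two-lineage hybrid zone: ~96 unlinked biallelic loci whose allele
frequencies differ strongly between a northern and a southern gene pool,
Hardy-Weinberg and linkage equilibrium within each pool, and Mendelian
crosses producing F1/F2 hybrids and first/second-generation backcrosses.

Two simulators produce hybrid genotypes and must agree in distribution:

* :func:`simulate_category` samples, per individual and locus, a gene-pool
  origin pair from the category's ``(p_NN, p_NS, p_SS)`` triple and then each
  gene copy from the corresponding pool frequency;
* :func:`simulate_pedigree_category` walks the explicit pedigree, sampling
  parental haplotypes and transmitting one gene copy per parent with free
  recombination.

For unlinked loci the two routes define the same genotype law, which the
test suite checks by chi-square goodness of fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import CATEGORIES, CATEGORY_PARENTS, category_triple
from .panel import MISSING, GenotypePanel


class ConfigError(ValueError):
    """Simulation configuration is infeasible or inconsistent."""


@dataclass
class LineageFrequencies:
    """Per-locus frequency of the southern (B) allele in each parental pool."""

    north: np.ndarray
    south: np.ndarray

    def __post_init__(self) -> None:
        self.north = np.asarray(self.north, dtype=float)
        self.south = np.asarray(self.south, dtype=float)
        if self.north.shape != self.south.shape:
            raise ConfigError("north/south frequency vectors must have equal length")
        for v in (self.north, self.south):
            if np.any((v < 0) | (v > 1)):
                raise ConfigError("allele frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.north.size

    def pool(self, name: str) -> np.ndarray:
        if name == "north":
            return self.north
        if name == "south":
            return self.south
        raise KeyError(f"unknown pool {name!r} (expected 'north' or 'south')")


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    ``diagnosticity`` is the minimum per-locus absolute frequency differential
    between the pools (1.0 = fully diagnostic loci, fixed 0 vs 1).
    """

    n_loci: int = 96
    diagnosticity: float = 0.9
    missing_rate: float = 0.0
    seed: int = 0
    sample_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.diagnosticity <= 1.0):
            raise ConfigError("diagnosticity must lie in (0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")


def make_lineage_frequencies(config: SimConfig, rng: np.random.Generator | None = None) -> LineageFrequencies:
    """Draw pool frequencies with differential >= ``config.diagnosticity``.

    The southern pool always carries the higher B-allele frequency, matching
    the coding convention (genotype counts southern alleles).  With
    ``diagnosticity == 1`` the loci are fully diagnostic: north fixed for A,
    south fixed for B.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    delta = config.diagnosticity
    if delta == 1.0:
        north = np.zeros(config.n_loci)
        south = np.ones(config.n_loci)
    else:
        north = rng.uniform(0.0, 1.0 - delta, size=config.n_loci)
        south = rng.uniform(north + delta, 1.0)
    return LineageFrequencies(north=north, south=south)


def _as_panel(genotypes: np.ndarray, label: str, prefix: str) -> GenotypePanel:
    n, n_loci = genotypes.shape
    return GenotypePanel(
        sample_ids=[f"{prefix}_{i:05d}" for i in range(n)],
        locus_ids=[f"L{j:03d}" for j in range(n_loci)],
        genotypes=genotypes.astype(np.int8),
        pop_labels=[label] * n,
    )


def simulate_parental(
    freqs: LineageFrequencies,
    pool: str,
    n: int,
    seed: int | np.random.Generator = 0,
    label: str | None = None,
) -> GenotypePanel:
    """Hardy-Weinberg genotypes from one pool: Binomial(2, pool freq) per locus."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = freqs.pool(pool)
    g = rng.binomial(2, p, size=(n, freqs.n_loci))
    label = label or pool
    return _as_panel(g, label, label)


def simulate_category(
    freqs: LineageFrequencies,
    category: str,
    n: int,
    seed: int | np.random.Generator = 0,
    label: str | None = None,
) -> GenotypePanel:
    """Hybrid-category genotypes via origin-pair sampling.

    Per individual x locus: draw the origin pair from the category triple,
    then NN -> Binomial(2, p_north), SS -> Binomial(2, p_south), NS -> one
    Bernoulli copy from each pool.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if category not in CATEGORIES:
        raise KeyError(f"unknown hybrid category {category!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_nn, p_ns, p_ss = category_triple(category)
    shape = (n, freqs.n_loci)
    u = rng.random(shape)
    # pair code: 0 = NN, 1 = NS, 2 = SS
    pair = np.where(u < p_nn, 0, np.where(u < p_nn + p_ns, 1, 2))
    g_nn = rng.binomial(2, freqs.north, size=shape)
    g_ss = rng.binomial(2, freqs.south, size=shape)
    g_ns = rng.binomial(1, freqs.north, size=shape) + rng.binomial(1, freqs.south, size=shape)
    g = np.choose(pair, [g_nn, g_ns, g_ss])
    label = label or category
    return _as_panel(g, label, label)


def _sample_haplotypes(
    category: str, n: int, freqs: LineageFrequencies, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """n individuals of a category as two (n, n_loci) haplotype arrays."""
    shape = (n, freqs.n_loci)
    if category == "WH":
        return rng.binomial(1, freqs.north, shape), rng.binomial(1, freqs.north, shape)
    if category == "MI":
        return rng.binomial(1, freqs.south, shape), rng.binomial(1, freqs.south, shape)
    mother, father = CATEGORY_PARENTS[category]
    return (
        _gamete(*_sample_haplotypes(mother, n, freqs, rng), rng),
        _gamete(*_sample_haplotypes(father, n, freqs, rng), rng),
    )


def _gamete(hap_a: np.ndarray, hap_b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted copy per locus, chosen uniformly (free recombination)."""
    pick = rng.integers(0, 2, size=hap_a.shape, dtype=np.int8)
    return np.where(pick == 0, hap_a, hap_b)


def simulate_pedigree_category(
    freqs: LineageFrequencies,
    category: str,
    n: int,
    seed: int | np.random.Generator = 0,
    label: str | None = None,
) -> GenotypePanel:
    """Hybrid-category genotypes via explicit gamete sampling through the pedigree.

    Equivalence oracle for :func:`simulate_category`: for unlinked loci both
    routes yield the same per-locus genotype distribution.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if category not in CATEGORIES:
        raise KeyError(f"unknown hybrid category {category!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hap_a, hap_b = _sample_haplotypes(category, n, freqs, rng)
    label = label or category
    return _as_panel(hap_a + hap_b, label, label)


def apply_missingness(
    panel: GenotypePanel, rate: float, seed: int | np.random.Generator = 0
) -> GenotypePanel:
    """Set each entry to MISSING independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ConfigError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return panel
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = panel.genotypes.copy()
    g[rng.random(g.shape) < rate] = MISSING
    return GenotypePanel(
        sample_ids=list(panel.sample_ids),
        locus_ids=list(panel.locus_ids),
        genotypes=g,
        pop_labels=list(panel.pop_labels),
        year=None if panel.year is None else list(panel.year),
    )


def concat_panels(panels: list[GenotypePanel]) -> GenotypePanel:
    """Stack panels typed on the same loci into one (sample ids made unique)."""
    if not panels:
        raise ConfigError("no panels to concatenate")
    loci = panels[0].locus_ids
    for p in panels[1:]:
        if p.locus_ids != loci:
            raise ConfigError("panels have different locus sets")
    sample_ids: list[str] = []
    for p in panels:
        for s in p.sample_ids:
            sample_ids.append(s if s not in sample_ids else f"{s}_dup{len(sample_ids)}")
    years: list[int | None] | None
    if any(p.year is not None for p in panels):
        years = []
        for p in panels:
            years.extend(p.year if p.year is not None else [None] * p.n_samples)
    else:
        years = None
    return GenotypePanel(
        sample_ids=sample_ids,
        locus_ids=list(loci),
        genotypes=np.vstack([p.genotypes for p in panels]),
        pop_labels=[lab for p in panels for lab in p.pop_labels],
        year=years,
    )


def simulate_population(
    freqs: LineageFrequencies,
    source: str,
    n: int,
    rng: np.random.Generator,
    label: str,
    year: int | None = None,
) -> GenotypePanel:
    """One named population from a pool ('north'/'south'), a hybrid category,
    or 'ancestral' (outgroup fixed for the ancestral A allele)."""
    if source in ("north", "south"):
        panel = simulate_parental(freqs, source, n, rng, label=label)
    elif source == "ancestral":
        panel = _as_panel(np.zeros((n, freqs.n_loci), dtype=np.int8), label, label)
    elif source in CATEGORIES:
        panel = simulate_category(freqs, source, n, rng, label=label)
    else:
        raise ConfigError(f"unknown population source {source!r}")
    if year is not None:
        panel = GenotypePanel(
            sample_ids=[f"{label}_{year}_{i:04d}" for i in range(n)],
            locus_ids=panel.locus_ids,
            genotypes=panel.genotypes,
            pop_labels=panel.pop_labels,
            year=[year] * n,
        )
    return panel
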