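"""Diversity statistics, Weir-Cockerham theta and the temporal-pooling rule.

The Weir-Cockerham implementation is checked against an independent oracle
that computes the variance components from the raw ANOVA sums of squares
over individual allele indicators (mean-squares route), not from the closed
formulas used in the package.
"""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from hybridpanel.panel import MISSING
from hybridpanel.popgen import (
    allelic_richness,
    compare_diversity,
    diversity_table,
    expected_heterozygosity,
    fst_permutation_test,
    observed_heterozygosity,
    temporal_pooling,
    weir_cockerham_fst,
)
from hybridpanel.simulate import LineageFrequencies, simulate_parental

from conftest import make_panel


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def wc_theta_anova_oracle(groups):
    """Weir-Cockerham theta via raw sums of squares over allele indicators.

    ``groups`` is a list (one per population) of per-locus genotype lists.
    Each genotype g in {0,1,2} is expanded to two allele indicators; the
    three mean squares (among populations, among individuals within
    populations, within individuals) give the variance components
    sigma2_P, sigma2_I, sigma2_G and theta = sigma2_P / total.
    Multilocus theta is the ratio of summed components.
    """
    n_loci = len(groups[0][0])
    num = den = 0.0
    for locus in range(n_loci):
        data = [[g[locus] for g in grp] for grp in groups]
        r = len(data)
        sizes = [len(d) for d in data]
        n = sum(sizes)
        # allele indicator pairs per individual
        y = [[(1 if g >= 1 else 0, 1 if g == 2 else 0) for g in d] for d in data]
        p_i = [sum(a + b for a, b in d) / (2 * len(d)) for d in y]
        p_bar = sum(sizes[i] * p_i[i] for i in range(r)) / n
        if p_bar in (0.0, 1.0):
            continue
        ssp = sum(2 * sizes[i] * (p_i[i] - p_bar) ** 2 for i in range(r))
        ssi = sum(
            2 * ((a + b) / 2 - p_i[i]) ** 2 for i in range(r) for (a, b) in y[i]
        )
        ssg = sum(
            (a - (a + b) / 2) ** 2 + (b - (a + b) / 2) ** 2
            for d in y for (a, b) in d
        )
        msp = ssp / (r - 1)
        msi = ssi / (n - r)
        msg = ssg / n
        n_c = (n - sum(s**2 for s in sizes) / n) / (r - 1)
        sigma_g = msg
        sigma_i = (msi - msg) / 2
        sigma_p = (msp - msi) / (2 * n_c)
        num += sigma_p
        den += sigma_p + sigma_i + sigma_g
    return num / den


def rarefaction_enumeration_oracle(count_b, copies, g):
    """Expected allele count in a subsample of g copies, by exhaustive
    enumeration of subsets of the gene copies."""
    pool = [1] * count_b + [0] * (copies - count_b)
    total = comb(copies, g)
    expect = 0.0
    for subset in combinations(range(copies), g):
        alleles = {pool[i] for i in subset}
        expect += len(alleles)
    return expect / total


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "genotypes,expected",
    [
        ([[0], [1], [1], [2]], 0.5),
        ([[1], [1], [1]], 1.0),
        ([[0], [1], [MISSING]], 0.5),  # over called genotypes only
    ],
)
def test_observed_heterozygosity_hand_counts(genotypes, expected):
    panel = make_panel(genotypes, ["P"] * len(genotypes))
    assert observed_heterozygosity(panel, "P")[0] == pytest.approx(expected)


def test_expected_heterozygosity_unbiased_formula():
    panel = make_panel([[0], [2]], ["P", "P"])
    # n=2 called, p=0.5: (2n/(2n-1)) * (1 - p^2 - q^2) = (4/3) * 0.5
    assert expected_heterozygosity(panel, "P")[0] == pytest.approx(2 / 3)


def test_expected_heterozygosity_monomorphic_zero():
    panel = make_panel([[0], [0], [0]], ["P"] * 3)
    assert expected_heterozygosity(panel, "P")[0] == 0.0


def test_expected_heterozygosity_hw_simulation():
    freqs = LineageFrequencies(north=np.full(20, 0.5), south=np.full(20, 0.5))
    panel = simulate_parental(freqs, "north", 5000, seed=8)
    he, _ = expected_heterozygosity(panel, "north")
    assert he == pytest.approx(0.5, abs=0.01)


def test_allelic_richness_fixed_locus_is_one():
    panel = make_panel([[2], [2], [2]], ["P"] * 3)
    assert allelic_richness(panel, "P", 2)[0] == pytest.approx(1.0)


def test_allelic_richness_hypergeometric_formula():
    # N=40 copies, N_B=10, g=20: AR = 2 - C(30,20)/C(40,20)
    genotypes = [[2]] * 5 + [[0]] * 15  # 10 B copies, 30 A copies
    panel = make_panel(genotypes, ["P"] * 20)
    expected = 2 - comb(30, 20) / comb(40, 20)
    assert allelic_richness(panel, "P", 20)[0] == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("count_b,copies,g", [(3, 8, 2), (3, 8, 4), (1, 6, 3), (4, 8, 5)])
def test_allelic_richness_matches_enumeration_oracle(count_b, copies, g):
    n_hom_b, rem = divmod(count_b, 2)
    genotypes = [[2]] * n_hom_b + [[1]] * rem + [[0]] * ((copies - count_b - rem) // 2)
    panel = make_panel(genotypes, ["P"] * len(genotypes))
    expected = rarefaction_enumeration_oracle(count_b, copies, g)
    assert allelic_richness(panel, "P", g)[0] == pytest.approx(expected, rel=1e-12)


def test_allelic_richness_monotone_in_g():
    genotypes = [[2], [1], [0], [1], [0]]
    panel = make_panel(genotypes, ["P"] * 5)
    values = [allelic_richness(panel, "P", g)[0] for g in range(1, 11)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
    # at g = N the rarefied count equals the observed allele count
    assert values[-1] == pytest.approx(2.0)


def test_compare_diversity_distinct_vs_single_group(rng):
    north = simulate_parental(
        LineageFrequencies(north=np.full(40, 0.05), south=np.full(40, 0.5)), "north", 30, rng
    )
    south = simulate_parental(
        LineageFrequencies(north=np.full(40, 0.05), south=np.full(40, 0.5)), "south", 30, rng
    )
    from hybridpanel.simulate import concat_panels

    panel = concat_panels([north, south])
    anova = compare_diversity(panel)
    assert (anova.loc[anova.statistic == "He", "p"] < 0.001).all()
    with pytest.raises(ValueError):
        compare_diversity(panel, ["north"])


def test_diversity_table_biallelic_bounds(two_pop_panel):
    table = diversity_table(two_pop_panel)
    assert ((table.Ho >= 0) & (table.Ho <= 1)).all()
    assert ((table.He >= 0) & (table.He <= 1)).all()
    assert ((table.AR >= 1) & (table.AR <= 2)).all()


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def test_theta_one_for_fixed_difference():
    panel = make_panel([[0, 0], [0, 0], [2, 2], [2, 2]], ["A", "A", "B", "B"])
    assert weir_cockerham_fst(panel, "A", "B").theta == pytest.approx(1.0)


def test_theta_matches_anova_mean_squares_oracle():
    ga = [[0, 1], [1, 2], [1, 0]]
    gb = [[2, 2], [2, 1], [1, 0]]
    panel = make_panel(ga + gb, ["A"] * 3 + ["B"] * 3)
    result = weir_cockerham_fst(panel, "A", "B")
    expected = wc_theta_anova_oracle([ga, gb])
    assert result.theta == pytest.approx(expected, abs=1e-12)


def test_theta_null_near_zero_and_may_be_negative(rng):
    freqs = LineageFrequencies(north=np.full(100, 0.5), south=np.full(100, 0.5))
    a = simulate_parental(freqs, "north", 25, rng, label="A")
    b = simulate_parental(freqs, "north", 25, rng, label="B")
    from hybridpanel.simulate import concat_panels

    theta = weir_cockerham_fst(concat_panels([a, b]), "A", "B").theta
    assert abs(theta) < 0.05


def test_theta_invariant_to_allele_relabeling_and_sample_order(rng):
    g = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
    labels = ["A"] * 5 + ["B"] * 5
    panel = make_panel(g, labels)
    theta = weir_cockerham_fst(panel, "A", "B").theta
    assert weir_cockerham_fst(make_panel(2 - g, labels), "A", "B").theta == pytest.approx(theta)
    perm = rng.permutation(10)
    shuffled = make_panel(g[perm], [labels[i] for i in perm])
    assert weir_cockerham_fst(shuffled, "A", "B").theta == pytest.approx(theta)


def test_fst_no_informative_loci_error():
    panel = make_panel([[0], [0], [0], [0]], ["A", "A", "B", "B"])
    with pytest.raises(ValueError, match="informative"):
        weir_cockerham_fst(panel, "A", "B")


def test_permutation_p_extreme_for_fixed_difference():
    panel = make_panel(
        [[0] * 8] * 10 + [[2] * 8] * 10, ["A"] * 10 + ["B"] * 10
    )
    theta, p = fst_permutation_test(panel, "A", "B", n_perm=99, seed=1)
    assert theta == pytest.approx(1.0)
    assert p == pytest.approx(1 / 100)


def test_permutation_reproducible(two_pop_panel):
    r1 = fst_permutation_test(two_pop_panel, "north", "south", n_perm=49, seed=5)
    r2 = fst_permutation_test(two_pop_panel, "north", "south", n_perm=49, seed=5)
    assert r1 == r2


# ---------------------------------------------------------------------------
# temporal pooling
# ---------------------------------------------------------------------------


def _yearly_panel(rng, shift):
    freqs_a = LineageFrequencies(north=np.full(40, 0.5), south=np.full(40, 0.5))
    freqs_b = LineageFrequencies(
        north=np.full(40, 0.5 + shift), south=np.full(40, 0.5)
    )
    a = simulate_parental(freqs_a, "north", 15, rng, label="loc")
    b = simulate_parental(freqs_b, "north", 15, rng, label="loc")
    from hybridpanel.simulate import concat_panels

    panel = concat_panels([a, b])
    return make_panel(
        panel.genotypes, ["loc"] * 30, year=[2018] * 15 + [2020] * 15
    )


def test_identical_years_pooled(rng):
    panel = _yearly_panel(rng, shift=0.0)
    pooled, report = temporal_pooling(panel, n_perm=199, seed=1)
    assert report.loc[0, "pooled"]
    assert pooled.populations == ["loc"]


def test_diverged_years_split(rng):
    panel = _yearly_panel(rng, shift=0.45)
    pooled, report = temporal_pooling(panel, n_perm=199, seed=1)
    assert not report.loc[0, "pooled"]
    assert set(pooled.populations) == {"loc_2018", "loc_2020"}


def test_single_year_location_passthrough():
    panel = make_panel([[0], [1], [2]], ["loc"] * 3, year=[2018] * 3)
    pooled, report = temporal_pooling(panel, n_perm=99)
    assert report.loc[0, "pooled"]
    assert pooled.pop_labels == panel.pop_labels
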