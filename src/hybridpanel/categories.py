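"""The 12 hybrid categories and their gene-pool origin-pair probabilities.

At a single locus each gene copy of a diploid descends from one of the two
parental gene pools, north (N) or south (S).  A hybrid category is fully
characterised, for unlinked loci, by the probability triple
``(p_NN, p_NS, p_SS)`` of the unordered origin pair of its two copies.

The triples follow from a gamete-origin recursion: a parent whose own triple
is ``(p_NN, p_NS, p_SS)`` transmits a north-pool gamete with probability
``g = p_NN + p_NS / 2``, and an offspring of parents with gamete-north
probabilities ``g1, g2`` has the triple

    p_NN = g1*g2,  p_NS = g1*(1-g2) + (1-g1)*g2,  p_SS = (1-g1)*(1-g2).

Categories: pure parental WH (north) and MI (south), F1, F2, first-generation
backcrosses bWH = WH x F1 and bMI = MI x F1, and the six second-generation
backcrosses of bWH / bMI with WH, MI and F1.  Later-generation hybrids (F3,
F4, ...) share the F2 triple and are not separate classes.
"""

from __future__ import annotations

import numpy as np

#: Pedigree of each category as a (parent, parent) pair; the two pure
#: parental pools are the recursion roots.
CATEGORY_PARENTS: dict[str, tuple[str, str]] = {
    "F1": ("WH", "MI"),
    "F2": ("F1", "F1"),
    "bWH": ("WH", "F1"),
    "bMI": ("MI", "F1"),
    "bWHxWH": ("bWH", "WH"),
    "bWHxMI": ("bWH", "MI"),
    "bWHxF1": ("bWH", "F1"),
    "bMIxMI": ("bMI", "MI"),
    "bMIxWH": ("bMI", "WH"),
    "bMIxF1": ("bMI", "F1"),
}

#: Canonical category order used by all result tables.
CATEGORIES: tuple[str, ...] = (
    "WH", "MI", "F1", "F2", "bWH", "bMI",
    "bWHxWH", "bWHxMI", "bWHxF1", "bMIxMI", "bMIxWH", "bMIxF1",
)

#: Origin pairs in canonical order.
ORIGIN_PAIRS: tuple[str, ...] = ("NN", "NS", "SS")


def gamete_north_prob(category: str) -> float:
    """Probability that a gamete of this category descends from the north pool."""
    p_nn, p_ns, _ = category_triple(category)
    return p_nn + p_ns / 2.0


def category_triple(category: str) -> tuple[float, float, float]:
    """(p_NN, p_NS, p_SS) for one category."""
    if category == "WH":
        return (1.0, 0.0, 0.0)
    if category == "MI":
        return (0.0, 0.0, 1.0)
    try:
        mother, father = CATEGORY_PARENTS[category]
    except KeyError:
        raise KeyError(f"unknown hybrid category {category!r}") from None
    g1 = gamete_north_prob(mother)
    g2 = gamete_north_prob(father)
    return (g1 * g2, g1 * (1.0 - g2) + (1.0 - g1) * g2, (1.0 - g1) * (1.0 - g2))


def category_table() -> dict[str, tuple[float, float, float]]:
    """All 12 categories mapped to their (p_NN, p_NS, p_SS) triples."""
    return {c: category_triple(c) for c in CATEGORIES}


def category_matrix() -> np.ndarray:
    """(12, 3) array of triples in :data:`CATEGORIES` x :data:`ORIGIN_PAIRS` order."""
    return np.array([category_triple(c) for c in CATEGORIES])
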