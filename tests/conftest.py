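import numpy as np
import pytest

from hybridpanel.panel import GenotypePanel


def make_panel(genotypes, pop_labels, year=None, locus_prefix="L"):
    """Build a small panel from a genotype list-of-lists."""
    g = np.asarray(genotypes, dtype=np.int8)
    return GenotypePanel(
        sample_ids=[f"s{i}" for i in range(g.shape[0])],
        locus_ids=[f"{locus_prefix}{j}" for j in range(g.shape[1])],
        genotypes=g,
        pop_labels=list(pop_labels),
        year=year,
    )


@pytest.fixture
def two_pop_panel():
    """Two populations with a fixed difference at locus 0, shared polymorphism at locus 1."""
    return make_panel(
        [[0, 1], [0, 1], [0, 0], [2, 1], [2, 0], [2, 1]],
        ["north", "north", "north", "south", "south", "south"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
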