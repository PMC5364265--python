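import numpy as np
import pytest

from idea.expression import RankedGeneList
from idea.gene_sets import GeneSetCollection


@pytest.fixture
def ten_gene_list():
    """Ranked list g01..g10 with strictly decreasing fold changes."""
    genes = [f"g{i:02d}".upper() for i in range(1, 11)]
    return RankedGeneList(
        genes=genes,
        log2fc=np.linspace(2.0, 0.2, 10),
        direction="up",
    )


@pytest.fixture
def ten_gene_universe(ten_gene_list):
    return set(ten_gene_list.genes)


@pytest.fixture
def small_collection():
    return GeneSetCollection(
        categories={"A": {"G01", "G02"}, "B": {"G08", "G09", "G10"}},
        universe={f"G{i:02d}" for i in range(1, 11)},
        source_labels={"A": ("x",), "B": ("x",)},
    )
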