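import numpy as np
import pytest

from mstmatch import (
    ClusterLabeling,
    GeneExpressionMatrix,
    MarkerGeneSet,
    SyntheticAtlas,
    simulate_cell_atlas_pair,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 cells, two clusters of 2."""
    gem = GeneExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["c1", "c2", "c3", "c4"],
        values=np.array([[1.0, 2, 0, 4], [0, 0, 0, 0], [5, 6, 7, 8]]),
        layer="counts",
    )
    labels = ClusterLabeling(["c1", "c2", "c3", "c4"], ["A", "A", "B", "B"])
    return gem, labels


@pytest.fixture
def markers3():
    return MarkerGeneSet(["g3", "g1"], group_of={"g3": "B", "g1": "A"})


@pytest.fixture(scope="session")
def small_atlas():
    """3-cluster atlas kept small so end-to-end unit tests stay fast."""
    return SyntheticAtlas(
        clusters=("C1", "C2", "C3"), cells_per_cluster=60, seed=42
    )


@pytest.fixture(scope="session")
def small_pair(small_atlas):
    return simulate_cell_atlas_pair(small_atlas, seed=42)
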