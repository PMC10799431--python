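import numpy as np
import pytest

from velogcn.datamodel import ExpressionDataset, NeighborGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(spliced, unspliced, **kwargs) -> ExpressionDataset:
    spliced = np.asarray(spliced, dtype=float)
    n, d = spliced.shape
    return ExpressionDataset(
        spliced=spliced,
        unspliced=np.asarray(unspliced, dtype=float),
        gene_names=kwargs.pop("gene_names", [f"g{i}" for i in range(d)]),
        cell_ids=kwargs.pop("cell_ids", [f"c{i}" for i in range(n)]),
        **kwargs,
    )


def make_graph(indices, distances=None) -> NeighborGraph:
    indices = np.asarray(indices, dtype=np.int64)
    if distances is None:
        distances = np.zeros(indices.shape, dtype=float)
    return NeighborGraph(indices=indices, distances=np.asarray(distances, dtype=float), k=indices.shape[1])


@pytest.fixture
def random_dataset(rng):
    """Small random dataset with strictly positive layers."""
    n, d = 40, 6
    return make_dataset(
        rng.gamma(2.0, 1.0, size=(n, d)) + 0.1,
        rng.gamma(2.0, 1.0, size=(n, d)) + 0.1,
    )
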