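import numpy as np
import pytest

from heatpass.graph_core import WeightedGraph, build_weighted_graph


def random_connected_graph(n: int, rng: np.random.Generator, density: float = 0.4):
    """Random weighted graph guaranteed connected (spanning chain + extras)."""
    W = np.zeros((n, n))
    for i in range(1, n):  # spanning chain
        W[i - 1, i] = W[i, i - 1] = rng.uniform(0.5, 2.0)
    extra = rng.random((n, n)) < density
    weights = rng.uniform(0.1, 1.0, (n, n))
    upper = np.triu(extra, k=1)
    W = np.maximum(W, np.where(upper | upper.T, (weights + weights.T) / 2, 0.0))
    np.fill_diagonal(W, 0.0)
    return build_weighted_graph(W)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def k2() -> WeightedGraph:
    return build_weighted_graph([(1, 2, 1.0)])


@pytest.fixture
def path3() -> WeightedGraph:
    return build_weighted_graph([(1, 2, 1.0), (2, 3, 1.0)])


@pytest.fixture
def star5() -> WeightedGraph:
    """K_{1,4}: hub 1 with four leaves."""
    return build_weighted_graph([(1, j, 1.0) for j in range(2, 6)])
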