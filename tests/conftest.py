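import numpy as np
import pytest

from spatialpanel.weights import (
    SpatialWeights,
    build_binary_weights,
    china_adjacency,
    row_standardize,
)


def binary_weights(mat: np.ndarray) -> SpatialWeights:
    """Wrap a dense 0/1 adjacency matrix as binary-style SpatialWeights."""
    mat = np.asarray(mat, dtype=float)
    n = mat.shape[0]
    return SpatialWeights(matrix=mat, style="binary",
                          region_order=list(range(1, n + 1)))


def cycle_graph(n: int) -> np.ndarray:
    mat = np.zeros((n, n))
    for i in range(n):
        mat[i, (i + 1) % n] = mat[i, (i - 1) % n] = 1.0
    return mat


def random_connected_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric adjacency with no isolated vertex (spanning path
    plus random extra edges)."""
    mat = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        mat[a, b] = mat[b, a] = 1.0
    extra = rng.random((n, n)) < 0.2
    extra = np.triu(extra, 1)
    mat[extra | extra.T] = 1.0
    np.fill_diagonal(mat, 0.0)
    return mat


@pytest.fixture(scope="session")
def china_adj():
    return china_adjacency()


@pytest.fixture(scope="session")
def china_W(china_adj):
    return row_standardize(build_binary_weights(china_adj))


@pytest.fixture(scope="session")
def china_W_binary(china_adj):
    return build_binary_weights(china_adj)


@pytest.fixture
def cycle4():
    return binary_weights(cycle_graph(4))
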