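import numpy as np
import pytest

from epjnmf.multinet import MultiNetwork, Partition


def clique_block_adjacency(sizes: list[int]) -> np.ndarray:
    """Adjacency of disjoint cliques with the given block sizes."""
    n = sum(sizes)
    A = np.zeros((n, n))
    start = 0
    for s in sizes:
        A[start : start + s, start : start + s] = 1.0
        start += s
    np.fill_diagonal(A, 0.0)
    return A


@pytest.fixture
def two_clique_net() -> tuple[MultiNetwork, Partition]:
    """Two disjoint 4-cliques, duplicated identically in two layers."""
    A = clique_block_adjacency([4, 4])
    net = MultiNetwork([A, A.copy()])
    truth = Partition(assignment=np.array([1, 1, 1, 1, 2, 2, 2, 2]))
    return net, truth


@pytest.fixture
def k4_net() -> MultiNetwork:
    """Single-layer unweighted complete graph on 4 vertices."""
    A = np.ones((4, 4)) - np.eye(4)
    return MultiNetwork([A])


def random_symmetric_layer(
    rng: np.random.Generator, n: int, density: float = 0.5
) -> np.ndarray:
    """Random non-negative symmetric zero-diagonal weight matrix."""
    W = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = np.triu(W, k=1)
    return W + W.T


def random_multinetwork(
    rng: np.random.Generator, n: int, M: int, density: float = 0.5
) -> MultiNetwork:
    return MultiNetwork([random_symmetric_layer(rng, n, density) for _ in range(M)])
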