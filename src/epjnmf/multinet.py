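"""Multilayer networks and module quality measures.

A multilayer (multiplex) network is an ordered collection of M weighted,
undirected graphs over one fixed vertex set of size n, stored as symmetric
non-negative adjacency matrices with zero diagonal. A *common module* is a
vertex set that is densely interconnected in every layer simultaneously;
its quality is measured by the geometric mean, across layers, of the
per-layer modularity density

    D_m(C) = (L(C, C) - L(C, V \\ C)) / sum_{v in C} d_vm ,

where ``L(A, B)`` sums edge weights over all ordered pairs (a, b) with a in
A and b in B (so intra-module weight is counted in both orientations) and
``d_vm`` is the weighted degree of v in layer m. With this convention the
whole vertex set of any layer with positive total weight scores exactly 1.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: relative tolerance for accepting a matrix as symmetric on load
SYMMETRY_RTOL = 1e-8


class MultiNetwork:
    """An ordered collection of weighted undirected layers on one vertex set.

    Parameters
    ----------
    layers
        Sequence of n x n adjacency matrices, one per layer. Each must be
        non-negative and symmetric within ``SYMMETRY_RTOL``; matrices are
        symmetrized as ``(W + W.T) / 2`` and self-loops are stripped on
        load (both with a logged warning when a change was needed).
    vertex_labels
        Optional identifiers aligned to matrix rows; defaults to
        ``v0 .. v{n-1}``.
    """

    def __init__(
        self,
        layers: Sequence[np.ndarray],
        vertex_labels: Sequence[str] | None = None,
    ) -> None:
        if len(layers) == 0:
            raise ValueError("a MultiNetwork needs at least one layer")
        mats: list[np.ndarray] = []
        n = None
        for idx, W in enumerate(layers):
            W = np.asarray(W, dtype=float)
            if W.ndim != 2 or W.shape[0] != W.shape[1]:
                raise ValueError(f"layer {idx} is not a square matrix: {W.shape}")
            if n is None:
                n = W.shape[0]
            elif W.shape[0] != n:
                raise ValueError(
                    f"layer {idx} has {W.shape[0]} vertices, expected {n}"
                )
            if np.any(W < 0):
                raise ValueError(f"layer {idx} has negative weights")
            asym = np.abs(W - W.T)
            tol = SYMMETRY_RTOL * np.maximum(1.0, np.abs(W))
            if np.any(asym > tol):
                raise ValueError(
                    f"layer {idx} is asymmetric beyond tolerance "
                    f"(max |w_ij - w_ji| = {asym.max():.3g})"
                )
            if np.any(asym > 0):
                logger.warning("layer %d symmetrized as (W + W.T)/2", idx)
                W = (W + W.T) / 2.0
            if np.any(np.diag(W) != 0):
                logger.warning("layer %d: self-loops stripped", idx)
                W = W.copy()
                np.fill_diagonal(W, 0.0)
            mats.append(W)
        self._layers = mats
        self._n = int(n)
        if vertex_labels is None:
            vertex_labels = [f"v{i}" for i in range(self._n)]
        if len(vertex_labels) != self._n:
            raise ValueError(
                f"{len(vertex_labels)} labels for {self._n} vertices"
            )
        self.vertex_labels: list[str] = [str(x) for x in vertex_labels]

    @property
    def n(self) -> int:
        """Number of vertices shared by all layers."""
        return self._n

    @property
    def M(self) -> int:
        """Number of layers."""
        return len(self._layers)

    @property
    def layers(self) -> list[np.ndarray]:
        return self._layers

    def layer(self, m: int) -> np.ndarray:
        """Adjacency matrix of layer ``m`` (0-based)."""
        if not 0 <= m < self.M:
            raise IndexError(f"layer index {m} out of range 0..{self.M - 1}")
        return self._layers[m]

    def layer_graph(self, m: int) -> nx.Graph:
        """Layer ``m`` as a :class:`networkx.Graph` (edges where w > 0)."""
        G = nx.from_numpy_array(self.layer(m))
        return G

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MultiNetwork(n={self.n}, M={self.M})"


@dataclass(frozen=True)
class Partition:
    """Hard assignment of n vertices to k non-empty modules.

    ``assignment[i]`` is the 1-based module id of vertex i. Every module
    id in ``1..k`` must occur at least once (non-emptiness).
    """

    assignment: np.ndarray
    k: int = field(default=0)

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim != 1 or a.size == 0:
            raise ValueError("assignment must be a non-empty 1-D vector")
        k = self.k if self.k else int(a.max())
        present = np.unique(a)
        if present[0] < 1 or present[-1] > k:
            raise ValueError(f"module ids must lie in 1..{k}, got {present}")
        if len(present) != k:
            missing = sorted(set(range(1, k + 1)) - set(present.tolist()))
            raise ValueError(f"empty modules: {missing}")
        object.__setattr__(self, "assignment", a)
        object.__setattr__(self, "k", k)

    @property
    def n(self) -> int:
        return self.assignment.size

    @property
    def X(self) -> np.ndarray:
        """Binary n x k indicator matrix (row sums equal 1)."""
        X = np.zeros((self.n, self.k), dtype=int)
        X[np.arange(self.n), self.assignment - 1] = 1
        return X

    def modules(self) -> list[np.ndarray]:
        """Vertex index arrays of the k modules, in module-id order."""
        return [np.flatnonzero(self.assignment == j + 1) for j in range(self.k)]

    @classmethod
    def from_indicator(cls, X: np.ndarray) -> "Partition":
        X = np.asarray(X)
        if np.any(X.sum(axis=1) != 1):
            raise ValueError("indicator rows must sum to 1 (hard partition)")
        return cls(assignment=X.argmax(axis=1) + 1, k=X.shape[1])

    @classmethod
    def from_module_sets(cls, sets: Iterable[Iterable[int]], n: int) -> "Partition":
        a = np.zeros(n, dtype=int)
        for j, members in enumerate(sets, start=1):
            a[np.asarray(list(members), dtype=int)] = j
        if np.any(a == 0):
            raise ValueError("module sets do not cover all vertices")
        return cls(assignment=a)


# ---------------------------------------------------------------------------
# structural measures
# ---------------------------------------------------------------------------


def vertex_degree(net: MultiNetwork, layer: int, v: int) -> float:
    """Weighted degree of vertex ``v`` in a layer: sum of incident weights."""
    W = net.layer(layer)
    if not 0 <= v < net.n:
        raise IndexError(f"vertex index {v} out of range 0..{net.n - 1}")
    return float(W[v].sum())


def betweenness(net: MultiNetwork, layer: int, v: int) -> float:
    """Shortest-path betweenness of ``v`` in a layer.

    Counts, over unordered vertex pairs (i, j) with i, j != v (each pair
    once), the fraction of shortest i-j paths passing through v. Paths are
    hop-count shortest paths on the layer's support (any pair with w > 0 is
    an edge); pairs with no connecting path contribute 0.
    """
    if not 0 <= v < net.n:
        raise IndexError(f"vertex index {v} out of range 0..{net.n - 1}")
    G = net.layer_graph(layer)
    bc = nx.betweenness_centrality(G, normalized=False)
    return float(bc[v])


def module_density(net: MultiNetwork, layer: int, C: Iterable[int]) -> float:
    """Edge density 2|E(C)| / (|C|(|C|-1)) of the subgraph induced by C.

    An edge is any vertex pair with strictly positive weight; weights do
    not otherwise enter. Returns 0 with a warning for |C| <= 1.
    """
    idx = np.asarray(sorted(set(int(i) for i in C)), dtype=int)
    if idx.size <= 1:
        warnings.warn(
            "module_density undefined for |C| <= 1; returning 0", stacklevel=2
        )
        return 0.0
    sub = net.layer(layer)[np.ix_(idx, idx)]
    n_edges = int(np.count_nonzero(np.triu(sub, k=1) > 0))
    return 2.0 * n_edges / (idx.size * (idx.size - 1))


def modularity_density_layer(
    net: MultiNetwork, layer: int, C: Iterable[int]
) -> float:
    """Modularity density of module C in one layer.

    ``(L(C,C) - L(C, V\\C)) / sum_{v in C} d_v`` with both orientations of
    intra-module edges counted in L(C,C). Equals 1 for the full vertex set
    of any layer with positive weight, and is negative for modules with
    more external than internal weight. Returns 0 with a warning when all
    vertices of C are isolated in the layer (zero denominator).
    """
    W = net.layer(layer)
    idx = np.asarray(sorted(set(int(i) for i in C)), dtype=int)
    if idx.size == 0:
        raise ValueError("module C must be non-empty")
    deg = W[idx].sum()
    if deg <= 0:
        warnings.warn(
            "all vertices of C isolated in this layer; connectivity set to 0",
            stacklevel=2,
        )
        return 0.0
    intra = W[np.ix_(idx, idx)].sum()  # both orientations
    inter = deg - intra
    return float((intra - inter) / deg)


def multi_connectivity(net: MultiNetwork, C: Iterable[int]) -> float:
    """Geometric mean of per-layer modularity densities of C.

    If any layer's modularity density is <= 0 the geometric mean is
    defined as 0, flooring the quality of modules that fail in some layer.
    """
    vals = [modularity_density_layer(net, m, C) for m in range(net.M)]
    if min(vals) <= 0:
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def partition_score(net: MultiNetwork, p: Partition) -> float:
    """Total multilayer quality of a partition: sum of module connectivities."""
    if p.n != net.n:
        raise ValueError(
            f"partition covers {p.n} vertices, network has {net.n}"
        )
    return float(sum(multi_connectivity(net, mod) for mod in p.modules()))
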