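"""Data-model validation and the multilayer quality measures."""

import numpy as np
import pytest

from epjnmf.multinet import (
    MultiNetwork,
    Partition,
    betweenness,
    module_density,
    modularity_density_layer,
    multi_connectivity,
    partition_score,
    vertex_degree,
)

from .conftest import clique_block_adjacency, random_multinetwork


class TestMultiNetworkValidation:
    def test_asymmetric_layer_rejected(self):
        W = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            MultiNetwork([W])

    def test_negative_weights_rejected(self):
        W = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            MultiNetwork([W])

    def test_layer_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="vertices"):
            MultiNetwork([np.zeros((3, 3)), np.zeros((4, 4))])

    def test_self_loops_stripped(self):
        W = np.eye(3) + clique_block_adjacency([3])
        net = MultiNetwork([W])
        assert np.all(np.diag(net.layer(0)) == 0)

    def test_tiny_asymmetry_symmetrized(self):
        W = np.array([[0.0, 1.0], [1.0 + 1e-12, 0.0]])
        net = MultiNetwork([W])
        assert np.array_equal(net.layer(0), net.layer(0).T)

    def test_label_count_checked(self):
        with pytest.raises(ValueError, match="labels"):
            MultiNetwork([np.zeros((3, 3))], vertex_labels=["a", "b"])


class TestPartition:
    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Partition(assignment=np.array([1, 1, 3, 3]), k=3)

    def test_indicator_roundtrip(self):
        p = Partition(assignment=np.array([1, 2, 2, 1, 3]))
        X = p.X
        assert np.all(X.sum(axis=1) == 1)
        assert Partition.from_indicator(X).assignment.tolist() == [1, 2, 2, 1, 3]

    def test_soft_indicator_rejected(self):
        X = np.array([[1, 1], [0, 1]])
        with pytest.raises(ValueError, match="hard"):
            Partition.from_indicator(X)


class TestVertexMeasures:
    def test_degree_complete_graph(self, k4_net):
        assert all(vertex_degree(k4_net, 0, v) == 3.0 for v in range(4))

    def test_degree_edgeless(self):
        net = MultiNetwork([np.zeros((4, 4))])
        assert vertex_degree(net, 0, 2) == 0.0

    def test_degree_weighted_hand_sum(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 2.0
        assert vertex_degree(MultiNetwork([W]), 0, 0) == pytest.approx(2.5)

    def test_degree_index_errors(self, k4_net):
        with pytest.raises(IndexError):
            vertex_degree(k4_net, 0, 7)
        with pytest.raises(IndexError):
            vertex_degree(k4_net, 2, 0)

    def test_betweenness_path_center(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        assert betweenness(MultiNetwork([W]), 0, 1) == pytest.approx(1.0)

    def test_betweenness_complete_graph_zero(self, k4_net):
        assert betweenness(k4_net, 0, 0) == pytest.approx(0.0)

    def test_betweenness_star_center(self):
        W = np.zeros((4, 4))
        W[0, 1:] = W[1:, 0] = 1.0
        assert betweenness(MultiNetwork([W]), 0, 0) == pytest.approx(3.0)


class TestModuleScores:
    def test_density_clique(self, k4_net):
        assert module_density(k4_net, 0, range(4)) == pytest.approx(1.0)

    def test_density_partial(self):
        # 4 vertices, 3 induced edges -> 2*3 / (4*3)
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            W[i, j] = W[j, i] = 1.0
        assert module_density(MultiNetwork([W]), 0, range(4)) == pytest.approx(0.5)

    def test_density_nonadjacent_pair(self):
        net = MultiNetwork([clique_block_adjacency([2, 2])])
        assert module_density(net, 0, [0, 2]) == 0.0

    def test_density_singleton_warns(self, k4_net):
        with pytest.warns(UserWarning, match="undefined"):
            assert module_density(k4_net, 0, [1]) == 0.0

    def test_modularity_density_full_graph_is_one(self):
        rng = np.random.default_rng(0)
        net = random_multinetwork(rng, 9, 1)
        assert modularity_density_layer(net, 0, range(9)) == pytest.approx(1.0)

    def test_modularity_density_isolated_clique(self):
        net = MultiNetwork([clique_block_adjacency([4, 4])])
        assert modularity_density_layer(net, 0, range(4)) == pytest.approx(1.0)

    def test_modularity_density_singleton_of_triangle(self):
        net = MultiNetwork([clique_block_adjacency([3])])
        assert modularity_density_layer(net, 0, [0]) == pytest.approx(-1.0)

    def test_modularity_density_isolated_vertices_warn(self):
        W = clique_block_adjacency([2, 2])
        W[2:, :] = 0.0
        W[:, 2:] = 0.0
        net = MultiNetwork([W])
        with pytest.warns(UserWarning, match="isolated"):
            assert modularity_density_layer(net, 0, [2, 3]) == 0.0

    def test_multi_connectivity_identical_layers(self):
        A = clique_block_adjacency([4, 4])
        net = MultiNetwork([A, A.copy()])
        single = MultiNetwork([A])
        C = range(4)
        assert multi_connectivity(net, C) == pytest.approx(
            modularity_density_layer(single, 0, C)
        )

    def test_multi_connectivity_geometric_mean(self):
        # layer 1: isolated 3-clique (D=1); layer 2 built so D=0.25
        A1 = clique_block_adjacency([3, 2])
        # intra weight 1 (L(C,C) = 2), external weight 1.2, degree sum 3.2
        # -> D = (2 - 1.2) / 3.2 = 0.25
        A2 = np.zeros((5, 5))
        for i, j, w in [(0, 1, 1.0), (2, 3, 0.6), (1, 4, 0.6)]:
            A2[i, j] = A2[j, i] = w
        net = MultiNetwork([A1, A2])
        d1 = modularity_density_layer(net, 0, [0, 1, 2])
        d2 = modularity_density_layer(net, 1, [0, 1, 2])
        assert d1 == pytest.approx(1.0)
        assert d2 == pytest.approx(0.25)
        assert multi_connectivity(net, [0, 1, 2]) == pytest.approx(0.5)

    def test_multi_connectivity_floors_at_zero(self):
        # C is a clique in layer 1 but has only external edges in layer 2
        A1 = clique_block_adjacency([3, 3])
        A2 = np.zeros((6, 6))
        A2[0, 3] = A2[3, 0] = 1.0
        net = MultiNetwork([A1, A2])
        assert multi_connectivity(net, [0, 1, 2]) == 0.0

    def test_partition_score_two_cliques(self, two_clique_net):
        net, truth = two_clique_net
        assert partition_score(net, truth) == pytest.approx(2.0)

    def test_partition_score_single_module(self, two_clique_net):
        net, _ = two_clique_net
        p = Partition(assignment=np.ones(8, dtype=int))
        assert partition_score(net, p) == pytest.approx(1.0)


class TestScoreProperties:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        net = random_multinetwork(rng, 10, 2)
        a = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1])
        p = Partition(assignment=a)
        base = partition_score(net, p)

        # relabel modules
        relabel = {1: 3, 2: 1, 3: 2}
        p2 = Partition(assignment=np.array([relabel[x] for x in a]))
        assert partition_score(net, p2) == pytest.approx(base, abs=1e-12)

        # permute vertices consistently in every layer
        perm = rng.permutation(10)
        net2 = MultiNetwork([W[np.ix_(perm, perm)] for W in net.layers])
        p3 = Partition(assignment=a[perm])
        assert partition_score(net2, p3) == pytest.approx(base, abs=1e-12)

    def test_planted_cliques_maximize_score(self):
        """Exhaustive check: the planted 2-clique split beats every other
        2-partition of the vertex set, in both layers jointly."""
        net = MultiNetwork([clique_block_adjacency([4, 4])] * 2)
        best, argbest = -np.inf, None
        n = 8
        for mask in range(1, 2 ** (n - 1)):  # vertex 0 fixed in module 1
            bits = [(mask >> i) & 1 for i in range(n)]
            if sum(bits) in (0, n):
                continue
            p = Partition(assignment=np.array(bits) + 1)
            s = partition_score(net, p)
            if s > best:
                best, argbest = s, tuple(bits)
        assert best == pytest.approx(2.0)
        assert argbest in [(0, 0, 0, 0, 1, 1, 1, 1), (1, 1, 1, 1, 0, 0, 0, 0)]
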