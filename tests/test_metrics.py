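import numpy as np
import pytest

from structconn.metrics import (
    DisconnectedGraphError,
    ModulePartition,
    UnreachablePairError,
    all_pairs_shortest_paths,
    betweenness_centrality,
    characteristic_path_length,
    global_clustering,
    global_efficiency,
    modularity_partition,
    nodal_apl,
    node_strength,
    participation_coefficient,
    small_world_sigma,
    weight_to_length,
    weighted_clustering,
)

from conftest import matrix_from
from _oracles import (
    betweenness_oracle,
    floyd_warshall_oracle,
    onnela_clustering_oracle,
    random_weighted_matrix,
)


def path_matrix():
    """A - B - C with unit weights."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1
    w[1, 2] = w[2, 1] = 1
    return matrix_from(w)


def star_matrix():
    """S4: center node 0 with 3 leaves, unit weights."""
    w = np.zeros((4, 4))
    for leaf in (1, 2, 3):
        w[0, leaf] = w[leaf, 0] = 1
    return matrix_from(w)


def complete_unit(n):
    return matrix_from(np.ones((n, n)) - np.eye(n))


class TestClosedForms:
    def test_strength_row_sums(self):
        m = matrix_from([[0, 2, 1], [2, 0, 0], [1, 0, 0]])
        assert np.array_equal(node_strength(m), [3, 2, 1])
        assert np.array_equal(node_strength(matrix_from(np.zeros((3, 3)))), [0, 0, 0])

    def test_strength_is_linear_in_weights(self):
        rng = np.random.default_rng(0)
        w = random_weighted_matrix(rng, 6)
        assert np.allclose(node_strength(matrix_from(2 * w)), 2 * node_strength(matrix_from(w)))

    def test_weight_to_length_inverse(self):
        m = matrix_from([[0, 2, 0], [2, 0, 4], [0, 4, 0]])
        lengths = weight_to_length(m)
        assert lengths[0, 1] == 0.5
        assert lengths[1, 2] == 0.25
        assert np.isinf(lengths[0, 2])
        assert lengths[0, 0] == 0

    def test_shortest_path_through_intermediate(self):
        # triangle with lengths AB=1, BC=1, AC=3 -> d(A,C)=2 via B
        w = np.array([[0, 1, 1 / 3], [1, 0, 1], [1 / 3, 1, 0]])
        dist = all_pairs_shortest_paths(weight_to_length(matrix_from(w)))
        assert dist.d[0, 2] == pytest.approx(2.0)

    def test_apl_star_and_path_and_complete(self):
        assert np.allclose(nodal_apl(all_pairs_shortest_paths(weight_to_length(star_matrix()))),
                           [1.0, 5 / 3, 5 / 3, 5 / 3])
        assert np.allclose(nodal_apl(all_pairs_shortest_paths(weight_to_length(path_matrix()))),
                           [1.5, 1.0, 1.5])
        assert np.allclose(nodal_apl(all_pairs_shortest_paths(weight_to_length(complete_unit(5)))),
                           np.ones(5))

    def test_apl_strict_policy_raises_on_unreachable(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1
        w[2, 3] = w[3, 2] = 1
        dist = all_pairs_shortest_paths(weight_to_length(matrix_from(w)))
        with pytest.raises(UnreachablePairError):
            nodal_apl(dist, policy="strict")
        apl = nodal_apl(dist, policy="reachable")
        assert np.allclose(apl, 1.0)

    def test_betweenness_path_and_star(self):
        assert np.array_equal(betweenness_centrality(path_matrix()), [0, 1, 0])
        assert np.array_equal(betweenness_centrality(star_matrix()), [3, 0, 0, 0])

    def test_clustering_triangle_and_star(self):
        tri = matrix_from([[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        assert np.allclose(weighted_clustering(tri), 1.0)
        assert np.allclose(weighted_clustering(star_matrix()), 0.0)

    def test_efficiency_complete_path_empty(self):
        assert global_efficiency(all_pairs_shortest_paths(weight_to_length(complete_unit(4)))) == pytest.approx(1.0)
        assert global_clustering(complete_unit(4)) == pytest.approx(1.0)
        assert global_efficiency(all_pairs_shortest_paths(weight_to_length(path_matrix()))) == pytest.approx(5 / 6)
        empty = matrix_from(np.zeros((4, 4)))
        assert global_efficiency(all_pairs_shortest_paths(weight_to_length(empty))) == 0.0

    def test_participation_closed_forms(self):
        # node 0 connects only within its own community -> PC = 0
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 5
        w[2, 3] = w[3, 2] = 5
        part = ModulePartition(np.array([0, 0, 1, 1]))
        pc = participation_coefficient(matrix_from(w), part)
        assert pc[0] == 0.0
        # 50/50 split across two communities -> 0.5
        w2 = np.zeros((3, 3))
        w2[0, 1] = w2[1, 0] = 2
        w2[0, 2] = w2[2, 0] = 2
        pc2 = participation_coefficient(matrix_from(w2), ModulePartition(np.array([0, 0, 1])))
        assert pc2[0] == pytest.approx(0.5)
        # even split across m communities -> 1 - 1/m
        m_comm = 5
        n = m_comm + 1
        w3 = np.zeros((n, n))
        w3[0, 1:] = 1
        w3[1:, 0] = 1
        part3 = ModulePartition(np.arange(n))
        pc3 = participation_coefficient(matrix_from(w3), part3)
        assert pc3[0] == pytest.approx(1 - 1 / m_comm)


class TestOracleEquivalence:
    def test_distances_match_floyd_warshall(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            w = random_weighted_matrix(rng, n, density=0.6)
            lengths = weight_to_length(matrix_from(w))
            dist = all_pairs_shortest_paths(lengths)
            oracle = floyd_warshall_oracle(lengths)
            finite = np.isfinite(oracle)
            assert np.array_equal(np.isfinite(dist.d), finite)
            assert np.max(np.abs(dist.d[finite] - oracle[finite])) < 1e-12

    def test_betweenness_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            w = random_weighted_matrix(rng, n, density=0.7)
            assert np.max(np.abs(
                betweenness_centrality(matrix_from(w)) - betweenness_oracle(w)
            )) < 1e-9

    def test_betweenness_splits_tied_shortest_paths(self):
        # 4-cycle with power-of-two weights: float arithmetic is exact, so
        # both implementation and oracle must see exactly 2 tied geodesics
        w = np.zeros((4, 4))
        for a, b in ((0, 1), (1, 2), (2, 3), (3, 0)):
            w[a, b] = w[b, a] = 2.0
        bc = betweenness_centrality(matrix_from(w))
        assert np.allclose(bc, 0.5)
        assert np.allclose(betweenness_oracle(w), 0.5)

    def test_clustering_matches_naive_triple_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            w = random_weighted_matrix(rng, n, density=0.7)
            assert np.max(np.abs(
                weighted_clustering(matrix_from(w)) - onnela_clustering_oracle(w)
            )) < 1e-12


class TestInvariances:
    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(4)
        w = random_weighted_matrix(rng, 8, density=0.7)
        perm = rng.permutation(8)
        wp = w[np.ix_(perm, perm)]
        m, mp = matrix_from(w), matrix_from(wp)
        assert np.allclose(node_strength(mp), node_strength(m)[perm])
        assert np.allclose(betweenness_centrality(mp), betweenness_centrality(m)[perm])
        assert np.allclose(weighted_clustering(mp), weighted_clustering(m)[perm])

    def test_weight_scaling_covariance(self):
        rng = np.random.default_rng(5)
        w = random_weighted_matrix(rng, 7, density=0.9)
        c = 3.7
        m, mc = matrix_from(w), matrix_from(c * w)
        assert np.allclose(node_strength(mc), c * node_strength(m))
        assert np.allclose(betweenness_centrality(mc), betweenness_centrality(m))
        assert np.allclose(weighted_clustering(mc), weighted_clustering(m))
        d = all_pairs_shortest_paths(weight_to_length(m))
        dc = all_pairs_shortest_paths(weight_to_length(mc))
        assert np.allclose(dc.d, d.d / c)
        assert global_efficiency(dc) == pytest.approx(c * global_efficiency(d))


class TestSigma:
    def _ws_matrix(self, seed, n=84, k=8, p=0.1):
        import networkx as nx

        g = nx.watts_strogatz_graph(n, k, p, seed=seed)
        rng = np.random.default_rng(seed)
        w = np.zeros((n, n))
        for a, b in g.edges:
            v = float(rng.uniform(50, 150))
            w[a, b] = w[b, a] = v
        return matrix_from(w)

    def test_small_world_ring_has_sigma_above_one(self):
        m = self._ws_matrix(seed=0)
        assert small_world_sigma(m, n_nulls=10, seed=1) > 1

    def test_sigma_deterministic_under_seed(self):
        m = self._ws_matrix(seed=1)
        s1 = small_world_sigma(m, n_nulls=5, seed=9)
        s2 = small_world_sigma(m, n_nulls=5, seed=9)
        assert s1 == s2
        assert small_world_sigma(m, n_nulls=5, seed=10) != s1

    def test_sigma_rejects_disconnected_input(self):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 1
        w[2, 3] = w[3, 2] = 1
        w[4, 5] = w[5, 4] = 1
        with pytest.raises(DisconnectedGraphError):
            small_world_sigma(matrix_from(w), n_nulls=3, seed=0)

    def test_characteristic_path_length_complete(self):
        dist = all_pairs_shortest_paths(weight_to_length(complete_unit(6)))
        assert characteristic_path_length(dist) == pytest.approx(1.0)


def test_louvain_partition_covers_all_nodes():
    rng = np.random.default_rng(6)
    w = random_weighted_matrix(rng, 20, density=0.4)
    part = modularity_partition(matrix_from(w), seed=0)
    assert len(part.assignment) == 20
    assert part.n_communities >= 1
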