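import numpy as np
import pytest

from percolome.core import ConnectomeError
from percolome.preprocess import binarize
from percolome.quantifiers import (
    community_metrics,
    compute_global_quantifiers,
    degree_distribution_summary,
    distance_metrics,
    largest_cluster_size,
    network_metrics,
    nodal_metrics,
    participation_coefficient,
    shortest_path_lengths,
    small_worldness,
)

from conftest import from_edges, make_matrix
from oracles import (
    brute_betweenness,
    brute_distances,
    brute_largest_component,
    brute_onnela_clustering,
    random_weighted_graph,
)


class TestShortestPaths:
    def test_unit_path_two_hops(self):
        m = from_edges(3, [(0, 1), (1, 2)])
        d = shortest_path_lengths(m)
        assert d[0, 2] == 2.0

    def test_weighted_triangle_no_shortcut(self):
        m = from_edges(3, [(0, 1, 1.0), (1, 2, 0.5), (0, 2, 0.5)])
        d = shortest_path_lengths(m)
        # direct lengths 1, 2, 2; two-hop detours are never shorter
        assert d[0, 1] == 1.0 and d[1, 2] == 2.0 and d[0, 2] == 2.0

    def test_disconnected_dyads_infinite(self):
        m = from_edges(4, [(0, 1), (2, 3)])
        d = shortest_path_lengths(m)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])


class TestDistanceMetrics:
    def test_unit_path_hand_enumeration(self):
        m = from_edges(3, [(0, 1), (1, 2)])
        out = distance_metrics(shortest_path_lengths(m))
        assert out["cpl"] == pytest.approx(4 / 3)
        assert out["global_efficiency"] == pytest.approx(5 / 6)
        assert out["radius"] == 1.0 and out["diameter"] == 2.0

    def test_infinite_pairs_omitted(self):
        m = from_edges(4, [(0, 1), (2, 3)])
        out = distance_metrics(shortest_path_lengths(m))
        assert out["cpl"] == 1.0 and out["diameter"] == 1.0

    def test_complete_unit_graph(self):
        m = from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        out = distance_metrics(shortest_path_lengths(m))
        assert out["cpl"] == out["global_efficiency"] == 1.0
        assert out["radius"] == out["diameter"] == 1.0

    def test_edgeless_flags_undefined(self):
        out = distance_metrics(shortest_path_lengths(make_matrix(np.zeros((3, 3)))))
        assert all(np.isnan(v) for v in out.values())


class TestLargestCluster:
    def test_connected_graph(self):
        m = from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        assert largest_cluster_size(m) == 5

    def test_multiple_components_union_find_oracle(self):
        edges = [(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (7, 8)]
        m = from_edges(9, edges)
        assert largest_cluster_size(m) == 4
        assert largest_cluster_size(m) == brute_largest_component(m.weights)

    def test_empty_graph_isolated_convention(self):
        assert largest_cluster_size(make_matrix(np.zeros((90, 90)))) == 1


class TestNodalMetrics:
    def test_star_degree_and_betweenness(self, star5):
        t = nodal_metrics(star5, metrics=["degree", "betweenness"])
        assert t["degree"].tolist() == [4, 1, 1, 1, 1]
        assert t["betweenness"].iloc[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert t["betweenness"].iloc[1:].eq(0).all()

    def test_triangle_clustering_and_local_efficiency(self):
        m = from_edges(3, [(0, 1), (1, 2), (0, 2)])
        t = nodal_metrics(m, metrics=["clustering", "local_efficiency"])
        np.testing.assert_allclose(t["clustering"], 1.0)
        np.testing.assert_allclose(t["local_efficiency"], 1.0)

    def test_strength_is_incident_weight_sum(self):
        m = from_edges(3, [(0, 1, 0.2), (0, 2, 0.3)])
        t = nodal_metrics(m, metrics=["strength"])
        assert t["strength"].iloc[0] == pytest.approx(0.5)

    def test_eigenvector_unit_norm_nonnegative(self, control_average):
        t = nodal_metrics(control_average, metrics=["eigenvector"])
        v = t["eigenvector"].to_numpy()
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert (v >= 0).all()

    def test_unknown_metric_rejected(self, star5):
        with pytest.raises(ConnectomeError, match="unknown"):
            nodal_metrics(star5, metrics=["pagerank"])


class TestOracleAgreement:
    """Spot-check against exhaustive path enumeration on small random graphs.

    The full 200-graph sweep runs in the acceptance suite; this keeps the
    unit suite fast while still exercising the same oracles.
    """

    @pytest.mark.parametrize("seed", range(25))
    def test_betweenness_cpl_clustering_components(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        w = random_weighted_graph(n, 0.5, rng)
        m = make_matrix(w)
        d = shortest_path_lengths(m)
        np.testing.assert_allclose(d, brute_distances(w), atol=1e-9)
        t = nodal_metrics(m, metrics=["betweenness", "clustering"])
        np.testing.assert_allclose(
            t["betweenness"], brute_betweenness(w), atol=1e-7
        )
        np.testing.assert_allclose(
            t["clustering"], brute_onnela_clustering(w), atol=1e-9
        )
        assert largest_cluster_size(m) == brute_largest_component(w)


class TestCommunityMetrics:
    def test_two_cliques_modularity_half(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        m = from_edges(8, edges)
        q, partition, p = community_metrics(m, seed=0, restarts=10)
        assert q == pytest.approx(0.5)
        assert len(set(partition[:4])) == 1 and len(set(partition[4:])) == 1
        assert partition[0] != partition[4]
        np.testing.assert_allclose(p, 0.0)  # all edges within own module

    def test_participation_even_split(self):
        # node 0 splits its strength equally across two foreign-module nodes
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 3] = w[3, 0] = 0.5
        w[1, 2] = w[2, 1] = 1.0
        w[3, 4] = w[4, 3] = 1.0
        partition = np.array([0, 0, 0, 1, 1])
        p = participation_coefficient(w, partition)
        assert p[0] == pytest.approx(0.5)

    def test_edgeless_flagged_undefined(self):
        q, _, p = community_metrics(make_matrix(np.zeros((4, 4))), restarts=2)
        assert np.isnan(q)
        assert not p.any()

    def test_best_q_beats_trivial_partition(self, control_average):
        q, _, _ = community_metrics(control_average, seed=1, restarts=10)
        assert q > 0.0


class TestNetworkMetrics:
    def test_binary_triangle_transitivity_one(self):
        m = binarize(from_edges(3, [(0, 1), (1, 2), (0, 2)]))
        assert network_metrics(m)["transitivity"] == pytest.approx(1.0)

    def test_star_transitivity_zero_assortativity_minus_one(self, star5):
        out = network_metrics(binarize(star5))
        assert out["transitivity"] == pytest.approx(0.0)
        assert out["assortativity"] == pytest.approx(-1.0)

    def test_four_cycle_no_triangles(self):
        m = binarize(from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)]))
        assert network_metrics(m)["transitivity"] == pytest.approx(0.0)

    def test_dyad_flagged_undefined(self):
        out = network_metrics(from_edges(2, [(0, 1)]))
        assert np.isnan(out["transitivity"])


class TestWeightedBinaryConsistency:
    @pytest.mark.parametrize("seed", range(5))
    def test_unit_weights_match_binary(self, seed):
        rng = np.random.default_rng(seed)
        w = (random_weighted_graph(8, 0.5, rng) != 0).astype(float)
        weighted = make_matrix(w, state="thresholded")
        binary = make_matrix(w, state="binarized")
        tw = nodal_metrics(weighted, seed=0, restarts=5)
        tb = nodal_metrics(binary, seed=0, restarts=5)
        for col in ("degree", "strength", "betweenness", "clustering", "local_efficiency"):
            np.testing.assert_allclose(tw[col], tb[col], atol=1e-9)


class TestDegreeDistribution:
    def test_regular_graph_no_tail(self):
        m = from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert degree_distribution_summary(m)["tail_fraction"] == 0.0

    def test_star_k19_tail(self):
        m = from_edges(10, [(0, i) for i in range(1, 10)])
        out = degree_distribution_summary(m)
        assert out["tail_fraction"] == pytest.approx(0.1)

    def test_empty_graph(self):
        assert degree_distribution_summary(make_matrix(np.zeros((5, 5))))["tail_fraction"] == 0.0


class TestSmallWorldness:
    def test_requires_large_component(self, star5):
        with pytest.raises(ConnectomeError, match="10 nodes"):
            small_worldness(star5)

    def test_watts_strogatz_exceeds_one(self):
        import networkx as nx

        g = nx.watts_strogatz_graph(60, 6, 0.1, seed=4)
        w = nx.to_numpy_array(g)
        m = make_matrix(w, state="binarized")
        assert small_worldness(m, n_null=5, seed=4) > 1.0


class TestGlobalQuantifierSet:
    def test_average_degree_and_density_exact(self, control_average):
        gq = compute_global_quantifiers(
            control_average, metrics=("n_edges", "avg_degree", "density")
        )
        assert gq.n_edges == 401
        assert gq.avg_degree == pytest.approx(2 * 401 / 90)
        assert gq.density == pytest.approx(401 / 4005)

    def test_radius_not_above_diameter(self, control_average):
        gq = compute_global_quantifiers(control_average, restarts=5)
        assert gq.radius <= gq.diameter
        assert gq.global_efficiency >= 0
        assert 0 <= gq.largest_cluster <= 90
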