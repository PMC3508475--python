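import networkx as nx
import numpy as np
import pytest

from connmat import (
    AnalysisConfig,
    build_graph,
    characteristic_path_length,
    count_components,
    degree_preserving_null,
    edge_weight_stats,
    euclidean_length_stats,
    global_efficiency,
    mean_clustering,
    modularity_partition,
    small_world_attributes,
)
from conftest import binary_graph, cm_from_upper, random_symmetric_cm
import oracles


class TestClosedFormIdentities:
    def test_complete_k4(self):
        g = binary_graph("complete", 4)
        assert characteristic_path_length(g) == pytest.approx(1.0)
        assert mean_clustering(g) == pytest.approx(1.0)
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_path_graph_p4(self):
        g = binary_graph("path", 4)
        assert characteristic_path_length(g) == pytest.approx(10 / 6)
        assert global_efficiency(g) == pytest.approx((1 + 0.5 + 1 / 3 + 1 + 0.5 + 1) / 6)

    def test_k4_minus_edge_clustering(self):
        cm = cm_from_upper([1, 1, 1, 1, 1, 0])  # (2,3) edge missing
        g = build_graph(cm, AnalysisConfig(density_percent=100))
        assert mean_clustering(g) == pytest.approx(5 / 6)

    def test_disconnected_graph_has_undefined_cpl(self):
        cm = cm_from_upper([1, 0, 0, 0, 0, 1])  # two disjoint edges
        g = build_graph(cm, AnalysisConfig(density_percent=100))
        assert characteristic_path_length(g) is None
        assert count_components(g) == 2

    def test_star_clustering_is_zero(self):
        assert mean_clustering(binary_graph("star", 4)) == 0.0

    def test_edgeless_graph_efficiency_zero(self):
        g = nx.empty_graph(5)
        assert global_efficiency(g) == 0.0
        assert count_components(g) == 5

    def test_ring_lattice_clustering_closed_form(self):
        # C = 3(k-2) / (4(k-1)) for a ring lattice; 0.5 at k=4
        assert mean_clustering(binary_graph("ring_lattice", 20, k=4)) == pytest.approx(0.5)


class TestWeightedDistances:
    def test_weighted_cpl_uses_inverse_weights(self):
        # two nodes joined by weight 0.5 -> distance 2
        cm = cm_from_upper([0.5, 0, 0, 0, 0, 0.25])
        g = build_graph(cm, AnalysisConfig(weighting="weighted", density_percent=34))
        # components: {0,1} d=2 and {2,3} d=4; disconnected -> CPL undefined
        assert characteristic_path_length(g) is None
        assert global_efficiency(g) == pytest.approx((0.5 + 0.25) / 6)


class TestModularity:
    def test_two_disjoint_cliques(self):
        g = binary_graph("two_cliques", 8)
        partition, q = modularity_partition(g)
        assert q == pytest.approx(0.5)
        assert partition.n_modules == 2
        assert len(set(partition.labels[:4])) == 1
        assert len(set(partition.labels[4:])) == 1

    def test_single_clique_single_module_q_zero(self):
        g = binary_graph("complete", 5).to_networkx()
        q = nx.community.modularity(g, [set(range(5))])
        assert q == pytest.approx(0.0)

    def test_edgeless_graph_q_undefined_singletons(self):
        partition, q = modularity_partition(nx.empty_graph(4))
        assert q is None
        assert partition.n_modules == 4

    def test_greedy_matches_exhaustive_maximum_on_joined_cliques(self):
        # two K4s joined by one edge: brute-force search over all partitions
        g = binary_graph("two_cliques", 8).to_networkx()
        g.add_edge(0, 4, weight=1.0)
        adj = nx.to_numpy_array(g)
        best = oracles.brute_best_modularity(adj)
        partition, q = modularity_partition(g)
        assert q == pytest.approx(best, abs=1e-10)
        assert partition.n_modules == 2

    def test_reported_q_at_least_singleton_module_q(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            cm = random_symmetric_cm(12, rng, density=0.4)
            g = build_graph(cm, AnalysisConfig(density_percent=100))
            if not g.edges:
                continue
            _, q = modularity_partition(g)
            assert -0.5 <= q <= 1.0
            assert q >= -1e-12  # singleton-module partition scores 0


class TestDegreePreservingNull:
    def test_degree_sequence_preserved_across_seeds(self):
        g = nx.connected_watts_strogatz_graph(40, 6, 0.2, seed=0)
        orig = sorted(d for _, d in g.degree())
        for seed in range(100):
            null = degree_preserving_null(g, swap_factor=5, seed=seed)
            assert sorted(d for _, d in null.degree()) == orig

    def test_complete_graph_returned_unchanged(self):
        g = binary_graph("complete", 5)
        with pytest.warns(UserWarning):
            null = degree_preserving_null(g, swap_factor=10, seed=0)
        assert set(null.edges()) == set(g.to_networkx().edges())

    def test_rewiring_destroys_lattice_clustering(self):
        # ring lattice has C = 0.5; rewired nulls should fall below in >= 95/100 runs
        g = binary_graph("ring_lattice", 20, k=4)
        below = sum(
            mean_clustering(degree_preserving_null(g, swap_factor=10, seed=s)) < 0.5
            for s in range(100)
        )
        assert below >= 95


class TestSmallWorldAttributes:
    def test_identity_null_gives_exact_unity(self):
        g = binary_graph("ring_lattice", 20, k=4)
        gamma, lam, sigma = small_world_attributes(g, n_null_networks=3, swap_factor=0, seed=0)
        assert gamma == 1.0
        assert lam == 1.0
        assert sigma == 1.0

    def test_random_graph_is_its_own_null(self):
        g = nx.erdos_renyi_graph(50, 0.2, seed=42)
        assert nx.is_connected(g)
        gamma, lam, _ = small_world_attributes(g, n_null_networks=20, swap_factor=10, seed=1)
        assert gamma == pytest.approx(1.0, abs=0.15)
        assert lam == pytest.approx(1.0, abs=0.15)

    def test_watts_strogatz_is_small_world(self):
        g = nx.connected_watts_strogatz_graph(100, 6, 0.1, seed=3)
        gamma, lam, sigma = small_world_attributes(g, n_null_networks=10, swap_factor=10, seed=4)
        assert sigma > 1.0

    def test_disconnected_input_gamma_only(self):
        cm = cm_from_upper([1, 0, 0, 0, 0, 1])
        g = build_graph(cm, AnalysisConfig(density_percent=100))
        gamma, lam, sigma = small_world_attributes(g, n_null_networks=2, swap_factor=2, seed=0)
        assert lam is None and sigma is None


class TestEdgeStats:
    def test_constant_weights(self):
        cm = cm_from_upper([1, 1, 1, 0, 0, 0])
        mean, sd = edge_weight_stats(cm)
        assert (mean, sd) == (1.0, 0.0)

    def test_population_sd_convention(self):
        cm = cm_from_upper([0.2, 0.4, 0, 0, 0, 0])
        mean, sd = edge_weight_stats(cm)
        assert mean == pytest.approx(0.3)
        assert sd == pytest.approx(0.1)  # population sd, divide by m

    def test_no_edges_undefined(self):
        assert edge_weight_stats(cm_from_upper([0.0] * 6)) == (None, None)

    def test_thresholded_graph_uses_retained_edges_only(self):
        cm = cm_from_upper([0.9, 0.8, 0.1, 0.1, 0.1, 0.1])
        g = build_graph(cm, AnalysisConfig(weighting="weighted", density_percent=34))
        mean, _ = edge_weight_stats(g)
        assert mean == pytest.approx(0.85)


class TestEuclideanStats:
    def test_three_four_five_edge(self):
        coords = np.array([[0, 0, 0], [3, 4, 0], [50, 0, 0], [0, 50, 0]], dtype=float)
        cm = cm_from_upper([1, 0, 0, 0, 0, 0], coords=coords)
        mean, sd = euclidean_length_stats(cm)
        assert (mean, sd) == (5.0, 0.0)

    def test_triangle_mean(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        cm = cm_from_upper([1, 1, 1], coords=coords)
        mean, _ = euclidean_length_stats(cm)
        assert mean == pytest.approx((1 + 1 + np.sqrt(2)) / 3)

    def test_no_edges(self):
        assert euclidean_length_stats(cm_from_upper([0.0] * 6)) == (None, None)


class TestOracleEquivalence:
    """Package metrics agree with brute-force enumeration on small graphs."""

    @pytest.mark.parametrize("seed", range(20))
    def test_random_small_graphs_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        cm = random_symmetric_cm(n, rng, density=float(rng.uniform(0.3, 1.0)))
        g = build_graph(cm, AnalysisConfig(density_percent=100))
        adj = (g.adjacency() != 0).astype(float)
        cpl = characteristic_path_length(g)
        expected_cpl = oracles.brute_cpl(adj)
        if expected_cpl is None:
            assert cpl is None
        else:
            assert cpl == pytest.approx(expected_cpl, abs=1e-10)
        assert mean_clustering(g) == pytest.approx(oracles.brute_mean_clustering(adj), abs=1e-10)
        assert global_efficiency(g) == pytest.approx(
            oracles.brute_global_efficiency(adj), abs=1e-10
        )
        assert count_components(g) == oracles.brute_components(adj)

    def test_efficiency_cpl_inequality_on_connected_graphs(self):
        # Jensen: mean(1/d) >= 1/mean(d)
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 10:
            cm = random_symmetric_cm(7, rng, density=0.7)
            g = build_graph(cm, AnalysisConfig(density_percent=100))
            cpl = characteristic_path_length(g)
            if cpl is None:
                continue
            assert global_efficiency(g) >= 1 / cpl - 1e-12
            checked += 1


class TestRelabelingInvariance:
    def test_metrics_invariant_under_node_permutation(self):
        rng = np.random.default_rng(9)
        cm = random_symmetric_cm(10, rng, density=0.6)
        perm = rng.permutation(10)
        w_perm = cm.weights[np.ix_(perm, perm)]
        cm_perm = cm_from_upper(w_perm[np.triu_indices(10, k=1)])
        g = build_graph(cm, AnalysisConfig(density_percent=100))
        gp = build_graph(cm_perm, AnalysisConfig(density_percent=100))
        assert mean_clustering(g) == pytest.approx(mean_clustering(gp), abs=1e-12)
        assert global_efficiency(g) == pytest.approx(global_efficiency(gp), abs=1e-12)
        assert count_components(g) == count_components(gp)
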