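import networkx as nx
import numpy as np
import pytest
from scipy.linalg import expm

from microcoalesce import (
    AbundanceTable,
    build_network,
    detect_modules,
    natural_connectivity,
    node_metrics,
    robustness_slope,
    spearman_matrix,
)
from microcoalesce.netstab import CooccurrenceNetwork, NetworkError


def net_from_graph(g):
    return CooccurrenceNetwork(g, rho_threshold=0.8, q_threshold=0.05, prevalence=0.5)


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        m = np.array([[1.0, 2, 3, 4, 5], [2, 4, 6, 8, 10], [5, 4, 3, 2, 1]])
        rho, _ = spearman_matrix(m)
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)

    def test_tied_ranks_hand_value(self):
        # average-rank handling: x=(1,2,2,3) vs y=(1,2,3,4) gives Pearson on
        # ranks (1, 2.5, 2.5, 4) vs (1, 2, 3, 4) = 4.5/sqrt(4.5*5) = 0.9487
        m = np.array([[1.0, 2, 2, 3, 5], [1, 2, 3, 4, 5]])
        rho, _ = spearman_matrix(m)
        from scipy.stats import spearmanr

        direct = spearmanr([1, 2, 2, 3], [1, 2, 3, 4]).statistic
        assert direct == pytest.approx(0.9487, abs=1e-4)
        assert rho[0, 1] == pytest.approx(spearmanr(m[0], m[1]).statistic)

    def test_too_few_samples_rejected(self):
        with pytest.raises(NetworkError):
            spearman_matrix(np.ones((3, 4)))


class TestBuildNetwork:
    def _table(self, rows, ids=None):
        rows = np.asarray(rows)
        ids = ids or [f"t{i}" for i in range(rows.shape[0])]
        return AbundanceTable(ids, [f"s{i}" for i in range(rows.shape[1])], rows)

    def test_covarying_pair_single_edge(self):
        table = self._table(
            [
                [1, 2, 3, 4, 5, 6],
                [2, 4, 6, 8, 10, 12],
                [5, 3, 6, 1, 4, 2],
            ]
        )
        net = build_network(table, table.sample_ids, rho_threshold=0.8)
        assert net.graph.number_of_edges() == 1
        assert net.graph.has_edge("t0", "t1")
        assert net.graph.number_of_nodes() == 3  # the independent taxon stays isolated

    def test_constant_taxon_excluded(self):
        table = self._table(
            [
                [3, 3, 3, 3, 3, 3],
                [1, 2, 3, 4, 5, 6],
                [2, 4, 6, 8, 10, 12],
            ]
        )
        net = build_network(table, table.sample_ids)
        assert "t0" not in net.graph.nodes

    def test_prevalence_rule(self):
        table = self._table(
            [
                [1, 2, 0, 0, 0, 0],  # present in 2/6 <= 50%
                [1, 2, 3, 4, 5, 6],
                [2, 4, 6, 8, 10, 12],
            ]
        )
        net = build_network(table, table.sample_ids, prevalence=0.5)
        assert "t0" not in net.graph.nodes

    def test_empty_group_rejected(self):
        table = self._table([[1, 2, 3, 4, 5]])
        with pytest.raises(NetworkError):
            build_network(table, [])


class TestNodeMetrics:
    def test_star_graph(self):
        g = nx.star_graph(3)  # center 0, leaves 1..3
        m = node_metrics(net_from_graph(g))
        assert m["degree"][0] == 3
        assert m["degree"][1] == 1
        assert m["neighborhood_connectivity"][1] == 3.0
        assert m["neighborhood_connectivity"][0] == 1.0

    def test_path_betweenness(self):
        g = nx.path_graph(3)  # a-b-c
        m = node_metrics(net_from_graph(g))
        assert m["betweenness"][1] == 1.0
        assert m["betweenness"][0] == 0.0


class TestDetectModules:
    def test_two_triangles(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        modules = detect_modules(net_from_graph(g))
        assert len(set(modules.values())) == 2
        assert modules[0] == modules[1] == modules[2]
        assert modules[3] == modules[4] == modules[5]

    def test_edgeless_graph_singletons(self):
        g = nx.empty_graph(4)
        modules = detect_modules(net_from_graph(g))
        assert len(set(modules.values())) == 4

    def test_deterministic(self):
        g = nx.karate_club_graph()
        a = detect_modules(net_from_graph(g), seed=0)
        b = detect_modules(net_from_graph(g), seed=0)
        assert a == b


class TestNaturalConnectivity:
    def test_edgeless_zero(self):
        assert natural_connectivity(np.zeros((5, 5))) == pytest.approx(0.0)

    def test_triangle_closed_form(self):
        a = np.ones((3, 3)) - np.eye(3)
        # eigenvalues 2, -1, -1 -> ln((e^2 + 2 e^-1)/3)
        assert natural_connectivity(a) == pytest.approx(0.9964, abs=1e-4)

    def test_path_closed_form(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        # eigenvalues sqrt(2), 0, -sqrt(2)
        assert natural_connectivity(a) == pytest.approx(0.5797, abs=1e-4)

    def test_matches_matrix_exponential_oracle(self):
        """NC agrees with ln(tr(expm(A))/n), an eigenvalue-free route."""
        rng = np.random.default_rng(0)
        for n in (5, 20, 50):
            a = (rng.random((n, n)) < 0.15).astype(float)
            a = np.triu(a, 1)
            a = a + a.T
            oracle = float(np.log(np.trace(expm(a)) / n))
            assert natural_connectivity(a) == pytest.approx(oracle, abs=1e-9)

    def test_edge_addition_strictly_increases(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(12, 0.3, seed=2)
        a = nx.to_numpy_array(g)
        before = natural_connectivity(a)
        empty = np.argwhere(np.triu(a == 0, 1))
        i, j = empty[rng.integers(len(empty))]
        a[i, j] = a[j, i] = 1
        assert natural_connectivity(a) > before

    def test_empty_matrix_rejected(self):
        with pytest.raises(NetworkError):
            natural_connectivity(np.zeros((0, 0)))


class TestRobustnessSlope:
    def test_edgeless_graph_flat(self):
        net = net_from_graph(nx.empty_graph(8))
        res = robustness_slope(net, n_iterations=20, seed=0)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert np.all(res.sd_connectivity == 0)

    def test_complete_graph_closed_form_slope(self):
        """K10 under 0..0.5 step 0.1 removal: every m-node induced subgraph is
        K_m, so the curve is deterministic and its OLS slope is -8.576."""
        net = net_from_graph(nx.complete_graph(10))
        res = robustness_slope(
            net, fractions=np.arange(0.0, 0.51, 0.1), n_iterations=50, seed=0
        )
        assert np.all(res.sd_connectivity < 1e-12)
        expected = [
            float(np.log((np.exp(m - 1) + (m - 1) * np.exp(-1)) / m)) for m in (10, 9, 8, 7, 6, 5)
        ]
        assert np.allclose(res.mean_connectivity, expected, atol=1e-9)
        assert res.slope == pytest.approx(-8.576, abs=0.05)

    def test_seeded_curve_reproducible(self):
        g = nx.gnp_random_graph(20, 0.2, seed=3)
        net = net_from_graph(g)
        a = robustness_slope(net, n_iterations=30, seed=5)
        b = robustness_slope(net, n_iterations=30, seed=5)
        assert np.array_equal(a.mean_connectivity, b.mean_connectivity)
        assert a.slope == b.slope

    def test_denser_graphs_decline_faster(self):
        """Among equal-order random graphs, higher edge density means a more
        negative robustness slope."""
        slopes = {}
        for p in (0.1, 0.4):
            vals = []
            for seed in range(3):
                g = nx.gnp_random_graph(25, p, seed=seed)
                vals.append(robustness_slope(net_from_graph(g), n_iterations=40, seed=seed).slope)
            slopes[p] = np.mean(vals)
        assert slopes[0.4] < slopes[0.1]

    def test_bad_fraction_rejected(self):
        net = net_from_graph(nx.complete_graph(6))
        with pytest.raises(NetworkError):
            robustness_slope(net, fractions=np.array([1.0]))
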