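import networkx as nx
import numpy as np
import pytest

from salinet.gradient import linear_trend
from salinet.stability import natural_connectivity, removal_simulation, stability_trend


def _oracle_nc(g: nx.Graph) -> float:
    """Independent oracle: plain eigendecomposition of the dense adjacency."""
    a = nx.to_numpy_array(g, weight=None)
    lam = np.linalg.eigvalsh(a)
    return float(np.log(np.mean(np.exp(lam))))


class TestNaturalConnectivity:
    def test_edgeless_is_zero(self):
        assert natural_connectivity(nx.empty_graph(7)) == 0.0

    def test_triangle_closed_form(self):
        # eigenvalues 2, -1, -1
        expected = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert natural_connectivity(nx.complete_graph(3)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.996311, abs=1e-6)

    def test_path3_closed_form(self):
        # eigenvalues sqrt(2), 0, -sqrt(2)
        expected = np.log((np.exp(np.sqrt(2)) + 1 + np.exp(-np.sqrt(2))) / 3)
        assert natural_connectivity(nx.path_graph(3)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.579674, abs=1e-6)

    def test_matches_oracle_on_random_graphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 20))
            g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.9), seed=int(rng.integers(1 << 30)))
            assert natural_connectivity(g) == pytest.approx(_oracle_nc(g), abs=1e-9)

    def test_disjoint_union_identity(self, rng):
        """nc of a disjoint union is the log of the size-weighted mean of the
        per-component exponential-eigenvalue means."""
        g1 = nx.gnp_random_graph(6, 0.5, seed=1)
        g2 = nx.gnp_random_graph(9, 0.4, seed=2)
        union = nx.disjoint_union(g1, g2)
        m1 = np.exp(natural_connectivity(g1))  # = mean exp eigenvalue
        m2 = np.exp(natural_connectivity(g2))
        expected = np.log((6 * m1 + 9 * m2) / 15)
        assert natural_connectivity(union) == pytest.approx(expected, abs=1e-10)

    def test_adding_edge_never_decreases(self, rng):
        for seed in range(10):
            g = nx.gnp_random_graph(10, 0.3, seed=seed)
            before = natural_connectivity(g)
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[int(rng.integers(len(non_edges)))]
            g.add_edge(u, v)
            assert natural_connectivity(g) >= before - 1e-12

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            natural_connectivity(nx.Graph())


class TestRemovalSimulation:
    def test_zero_fraction_is_identity(self):
        g = nx.karate_club_graph()
        res = removal_simulation(g, [0.0], n_replicates=5, seed=0)
        assert np.allclose(res.records["avg_degree"], 2 * g.number_of_edges() / 34)
        assert res.records["natural_connectivity"].std() == 0.0

    def test_complete_graph_closed_form(self):
        g = nx.complete_graph(12)
        res = removal_simulation(g, [0.25], n_replicates=10, seed=1)
        # removing k nodes from K_n leaves K_{n-k}: avg degree n-k-1 exactly
        assert np.allclose(res.records["avg_degree"], 12 - 3 - 1)

    def test_star_bimodal_matches_enumeration(self):
        """Removing 2 of 6 nodes of a star: the hub survives w.p. C(5,2)/C(6,2)
        = 2/3; survivors form a star (avg degree 2*4/6... computed exactly)
        or an edgeless graph."""
        g = nx.star_graph(5)  # 6 nodes, hub 0
        res = removal_simulation(g, [1 / 3], n_replicates=3000, seed=2)
        deg = res.records["avg_degree"].to_numpy()
        hub_dead = deg == 0.0
        assert hub_dead.mean() == pytest.approx(1 / 3, abs=0.03)
        assert np.allclose(deg[~hub_dead], 2 * 3 / 4)  # star with 3 leaves left

    def test_removing_all_nodes_rejected(self):
        with pytest.raises(ValueError, match="remove all"):
            removal_simulation(nx.path_graph(3), [0.99], n_replicates=1)

    def test_isolated_survivors_counted(self):
        g = nx.star_graph(4)
        res = removal_simulation(g, [0.2], n_replicates=200, seed=3)
        # when the hub is removed, 4 isolated nodes remain: avg degree 0 over N=4
        assert (res.records["avg_degree"] == 0).any()


class TestStabilityTrend:
    def test_identical_networks_flat(self):
        g = nx.gnp_random_graph(20, 0.3, seed=0)
        results = [removal_simulation(g, [0.2], 20, seed=5) for _ in range(4)]
        trend = stability_trend(results, [1.0, 5.0, 10.0, 20.0], 0.2)
        assert trend.slope == pytest.approx(0.0, abs=1e-12)

    def test_planted_density_decay_detected(self):
        rng = np.random.default_rng(4)
        nets, sals = [], [2.0, 6.0, 10.0, 14.0, 18.0]
        for i, p in enumerate([0.5, 0.4, 0.3, 0.2, 0.1]):
            nets.append(nx.gnp_random_graph(40, p, seed=i))
        results = [
            removal_simulation(g, [0.3], 40, seed=int(rng.integers(1 << 30))) for g in nets
        ]
        for metric in ("avg_degree", "natural_connectivity"):
            trend = stability_trend(results, sals, 0.3, metric)
            assert trend.slope < 0
            assert trend.p_value < 0.05

    def test_two_networks_rejected(self):
        g = nx.path_graph(5)
        results = [removal_simulation(g, [0.2], 5, seed=0)] * 2
        with pytest.raises(ValueError, match="3 networks"):
            stability_trend(results, [1.0, 2.0], 0.2)
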