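"""Global and per-node network attributes against closed forms and the
brute-force path-enumeration oracle."""

import networkx as nx
import numpy as np
import pytest

import _bruteforce as bf
from conftest import make_network, random_connected_graph
from zoonet import (
    SignedInteractionNetwork,
    betweenness_centrality,
    closeness_centrality,
    compare_classes,
    global_attributes,
    local_clustering,
    node_degree,
    node_table,
)


def complete(n):
    return make_network([(i, j, 0.9) for i in range(n) for j in range(i + 1, n)])


def star(n):
    return make_network([(0, i, 0.9) for i in range(1, n)])


def path(n):
    return make_network([(i, i + 1, 0.9) for i in range(n - 1)])


class TestClosedForms:
    def test_complete_graph_k5(self):
        ga = global_attributes(complete(5))
        assert ga.density == pytest.approx(1.0)
        assert ga.clustering_coefficient == pytest.approx(1.0)
        assert ga.network_centralization == pytest.approx(0.0)
        assert ga.characteristic_path_length == pytest.approx(1.0)
        assert ga.shortest_paths_count == 20
        assert ga.shortest_paths_pct == pytest.approx(100.0)
        assert ga.heterogeneity == pytest.approx(0.0)
        assert ga.avg_neighbors == pytest.approx(4.0)

    def test_five_node_star(self):
        ga = global_attributes(star(5))
        assert ga.density == pytest.approx(0.4)
        assert ga.network_centralization == pytest.approx(1.0)
        assert ga.clustering_coefficient == pytest.approx(0.0)
        assert ga.heterogeneity == pytest.approx(0.75)
        assert ga.characteristic_path_length == pytest.approx(1.6)

    def test_four_node_path(self):
        ga = global_attributes(path(4))
        assert ga.density == pytest.approx(0.5)
        assert ga.network_centralization == pytest.approx(1.0 / 3.0)
        assert ga.characteristic_path_length == pytest.approx(10.0 / 6.0)
        assert ga.heterogeneity == pytest.approx(1.0 / 3.0)
        assert ga.shortest_paths_count == 12
        assert ga.shortest_paths_pct == pytest.approx(100.0)

    def test_cycles_and_cliques_have_zero_centralization(self):
        for net in (complete(4), complete(7),
                    make_network([(i, (i + 1) % 6, 0.5) for i in range(6)])):
            assert global_attributes(net).network_centralization == pytest.approx(0.0)


class TestNodeMetrics:
    def test_degree(self):
        assert node_degree(star(5), 0) == 4
        assert node_degree(star(5), 3) == 1
        assert all(node_degree(complete(6), v) == 5 for v in range(6))
        assert node_degree(make_network([], nodes=["x"]), "x") == 0

    def test_unknown_taxon(self):
        with pytest.raises(KeyError):
            node_degree(star(4), "nope")

    def test_local_clustering(self):
        triangle = complete(3)
        assert local_clustering(triangle, 0) == pytest.approx(1.0)
        assert local_clustering(star(5), 0) == pytest.approx(0.0)
        net = make_network([("v", "a", 1), ("v", "b", 1), ("v", "c", 1), ("a", "b", 1)])
        assert local_clustering(net, "v") == pytest.approx(1.0 / 3.0)

    def test_closeness(self):
        p3 = path(3)
        assert closeness_centrality(p3, 0) == pytest.approx(2.0 / 3.0)
        assert closeness_centrality(p3, 1) == pytest.approx(1.0)
        assert closeness_centrality(complete(5), 2) == pytest.approx(1.0)
        assert closeness_centrality(make_network([], nodes=["x"]), "x") == 0.0

    def test_betweenness(self):
        assert betweenness_centrality(path(3), 1) == pytest.approx(1.0)
        assert betweenness_centrality(complete(5), 0) == pytest.approx(0.0)
        s5 = star(5)
        assert betweenness_centrality(s5, 0) == pytest.approx(1.0)
        assert betweenness_centrality(s5, 2) == pytest.approx(0.0)

    def test_weighted_mode_uses_abs_r_as_length(self):
        # a—b short (|r|=0.2), b—c long (|r|=0.9): d(a,c) = 1.1
        net = make_network([("a", "b", 0.2), ("b", "c", -0.9)])
        assert closeness_centrality(net, "a", "weighted") == pytest.approx(
            2.0 / (0.2 + 1.1)
        )


class TestBruteForceAgreement:
    def test_metrics_match_path_enumeration(self, rng):
        for _ in range(60):
            g = random_connected_graph(rng)
            net = SignedInteractionNetwork.from_graph(
                nx.Graph([(u, v, {"r": float(rng.uniform(-1, 1)) or 0.5})
                          for u, v in g.edges])
            )
            adj = bf.adjacency(net.graph.edges, net.graph.nodes)
            ga = global_attributes(net)
            ref = bf.global_attributes(adj)
            for key, want in ref.items():
                assert getattr(ga, key) == pytest.approx(want, abs=1e-9), key
            nbc = bf.betweenness(adj)
            for v in net.graph.nodes:
                assert node_degree(net, v) == bf.degree(adj, v)
                assert local_clustering(net, v) == pytest.approx(bf.clustering(adj, v), abs=1e-9)
                assert closeness_centrality(net, v) == pytest.approx(bf.closeness(adj, v), abs=1e-9)
                assert betweenness_centrality(net, v) == pytest.approx(nbc[v], abs=1e-9)


class TestInvariances:
    def test_sign_flip_leaves_topology_metrics_unchanged(self, rng):
        g = random_connected_graph(rng)
        edges = [(u, v, float(rng.uniform(0.3, 1.0))) for u, v in g.edges]
        net_pos = make_network(edges)
        net_neg = make_network([(u, v, -r) for u, v, r in edges])
        a, b = global_attributes(net_pos), global_attributes(net_neg)
        for key in ("clustering_coefficient", "network_centralization", "density",
                    "heterogeneity", "characteristic_path_length"):
            assert getattr(a, key) == pytest.approx(getattr(b, key))

    def test_full_coverage_iff_connected(self):
        connected = path(5)
        assert global_attributes(connected).shortest_paths_pct == pytest.approx(100.0)
        split = make_network([(0, 1, 1), (2, 3, 1), (3, 4, 1), (2, 4, 1)])
        assert global_attributes(split).shortest_paths_pct < 100.0

    def test_isolated_nodes_excluded_from_global_n(self):
        net = make_network([(0, 1, 1), (1, 2, 1)], nodes=[0, 1, 2, "iso"])
        ga = global_attributes(net)
        assert ga.n_nodes == 3 and ga.n_isolated_excluded == 1
        ga_all = global_attributes(net, include_isolated=True)
        assert ga_all.n_nodes == 4


class TestNodeTable:
    def test_star_hub_tops_ndc_and_nbc(self):
        tbl = node_table(star(6))
        assert tbl["NDC"].idxmax() == 0
        assert tbl["NBC"].idxmax() == 0
        assert (tbl.drop(index=0)["NBC"] == 0).all()

    def test_k4_symmetry(self):
        tbl = node_table(complete(4))
        assert (tbl["NDC"] == 3).all()
        assert np.allclose(tbl["NCC"], 1.0)
        assert np.allclose(tbl["NBC"], 0.0)
        assert np.allclose(tbl["CCF"], 1.0)

    def test_empty_network(self):
        assert node_table(make_network([])).empty

    def test_isolated_node_row(self):
        tbl = node_table(make_network([(0, 1, 1)], nodes=[0, 1, "iso"]))
        row = tbl.loc["iso"]
        assert row["NDC"] == 0 and row["NCC"] == 0.0 and row["CCF"] == 0.0

    def test_sorting_deterministic(self):
        tbl = node_table(star(5), sort_by="NDC")
        assert list(tbl.index[:1]) == [0]
        assert list(tbl.index[1:]) == [1, 2, 3, 4]  # ties by name


class TestCompareClasses:
    def test_identical_networks_identical_columns(self):
        table, _ = compare_classes({"x": star(6), "y": star(6)})
        assert np.allclose(table["x"].astype(float), table["y"].astype(float))

    def test_edgeless_network_isolated_failure(self):
        table, top = compare_classes(
            {"ok": complete(4), "empty": make_network([], nodes=[0, 1, 2])}
        )
        assert np.isfinite(table["ok"]["Characteristic path length"])
        assert np.isnan(table["empty"]["Characteristic path length"])
        assert top["empty"].empty

    def test_threshold_selection(self):
        table, top = compare_classes(
            {"a": star(15), "b": complete(4)}, ndc_cut=10, ncc_cuts=2.0, nbc_cut=2.0
        )
        assert list(top["a"].index) == [0]  # only the hub exceeds NDC > 10
        assert top["b"].empty
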