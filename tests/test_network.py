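import networkx as nx
import numpy as np
import pytest

from exomirnet.network import (
    build_bipartite,
    build_graph,
    mcl_cluster,
    select_hubs,
    topology_scores,
)
from exomirnet.target_screen import TargetPrediction


def _edges(*pairs):
    return [(a, b, 1.0) for a, b in pairs]


def _triangle(prefix):
    a, b, c = f"{prefix}1", f"{prefix}2", f"{prefix}3"
    return _edges((a, b), (b, c), (a, c))


def _k(nodes):
    return [(a, b, 1.0) for i, a in enumerate(nodes) for b in nodes[i + 1:]]


class TestBuildGraph:
    def test_whitelist_restriction(self):
        g = build_graph(_edges(("A", "B"), ("B", "C"), ("A", "C")), {"A", "B"})
        assert set(g.nodes) == {"A", "B"}
        assert set(g.edges) == {("A", "B")}

    def test_empty_whitelist_empty_graph(self):
        g = build_graph(_edges(("A", "B")), set())
        assert len(g.nodes) == 0

    def test_isolated_whitelist_nodes_retained(self):
        g = build_graph(_edges(("A", "B")), {"A", "B", "Z"})
        assert "Z" in g.nodes and g.degree["Z"] == 0

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            build_graph([("A", "A", 1.0)])

    def test_module_fixture_connected_component(self, hub_fixture):
        g = build_graph(hub_fixture["module_edges"])
        assert len(g.nodes) == 12
        assert nx.is_connected(g)


class TestMcl:
    def test_two_disjoint_triangles_two_clusters(self):
        g = build_graph(_triangle("a") + _triangle("b"))
        clusters = mcl_cluster(g).clusters()
        assert sorted(map(sorted, clusters)) == [
            ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        ]

    def test_complete_graph_single_cluster(self):
        g = build_graph(_k(["a", "b", "c", "d"]))
        assert len(mcl_cluster(g).clusters()) == 1

    def test_barbell_splits_into_blocks(self):
        left, right = ["l1", "l2", "l3", "l4"], ["r1", "r2", "r3", "r4"]
        g = build_graph(_k(left) + _k(right) + _edges(("l1", "r1")))
        clusters = {frozenset(c) for c in mcl_cluster(g, inflation=3.0).clusters()}
        assert clusters == {frozenset(left), frozenset(right)}

    def test_partition_and_input_order_invariance(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i}" for i in range(30)]
        edges = [(a, b, float(rng.uniform(0.2, 1)))
                 for i, a in enumerate(nodes) for b in nodes[i + 1:]
                 if rng.random() < 0.12]
        g1 = build_graph(edges)
        order = list(edges)
        rng.shuffle(order)
        g2 = build_graph(order)
        c1, c2 = mcl_cluster(g1), mcl_cluster(g2)
        assert c1.cluster_of == c2.cluster_of
        assert sorted(c1.cluster_of) == sorted(g1.nodes)  # total partition

    def test_clusters_refine_connected_components(self):
        rng = np.random.default_rng(6)
        comps = []
        edges = []
        for c in range(3):
            nodes = [f"c{c}n{i}" for i in range(8)]
            comps.append(set(nodes))
            edges += [(a, b, 1.0) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                      if rng.random() < 0.5]
        g = build_graph(edges)
        for cluster in mcl_cluster(g).clusters():
            assert any(cluster <= comp for comp in comps)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mcl_cluster(nx.Graph())


def brute_force_topology(g):
    deg = {v: sum(1 for _ in g.neighbors(v)) for v in g.nodes}
    nc = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        nc[v] = sum(deg[u] for u in nbrs) / len(nbrs) if nbrs else 0.0
    return deg, nc


class TestTopology:
    def test_triangle_closed_form(self):
        g = build_graph(_triangle("t"))
        scores = topology_scores(g)
        assert all(scores.degree[v] == 2 for v in g.nodes)
        assert all(scores.neighborhood_connectivity[v] == 2.0 for v in g.nodes)

    def test_star_closed_form(self):
        g = build_graph(_edges(("hub", "l1"), ("hub", "l2"), ("hub", "l3"), ("hub", "l4")))
        s = topology_scores(g)
        assert s.degree["hub"] == 4 and s.neighborhood_connectivity["hub"] == 1.0
        assert all(s.degree[f"l{i}"] == 1 and s.neighborhood_connectivity[f"l{i}"] == 4.0
                   for i in range(1, 5))

    def test_isolated_node_zero_convention(self):
        g = build_graph(_edges(("A", "B")), {"A", "B", "Z"})
        s = topology_scores(g)
        assert (s.degree["Z"], s.neighborhood_connectivity["Z"]) == (0, 0.0)

    def test_degree_sum_is_twice_edges(self):
        g = build_graph(_k([f"n{i}" for i in range(10)]))
        s = topology_scores(g)
        assert sum(s.degree.values()) == 2 * g.number_of_edges()

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(3, 25))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.6)), seed=int(rng.integers(1e6)))
            scores = topology_scores(g)
            deg, nc = brute_force_topology(g)
            assert scores.degree == deg
            for v in g.nodes:
                assert scores.neighborhood_connectivity[v] == pytest.approx(nc[v])


class TestHubsAndBipartite:
    def test_printed_lists_union_fifteen(self, hub_fixture):
        hubs = select_hubs(hub_fixture["pathway_genes"], hub_fixture["module_genes"])
        assert len(hub_fixture["pathway_genes"]) == 9
        assert len(hub_fixture["module_genes"]) == 12
        assert len(hubs) == 15

    def test_union_is_idempotent_and_disjoint_adds(self):
        assert select_hubs({"a", "b"}, {"a", "b"}) == {"a", "b"}
        assert len(select_hubs({"a", "b", "c"}, {"d", "e", "f", "g"})) == 7

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            select_hubs([], [])

    def test_bipartite_fixture_nodes(self, hub_fixture):
        hubs = select_hubs(hub_fixture["pathway_genes"], hub_fixture["module_genes"])
        net = build_bipartite(hubs, hub_fixture["predictions"])
        assert len(net.genes) == 15
        assert len(net.mirnas) == 21

    def test_no_touching_predictions_empty_edges(self):
        net = build_bipartite({"G1"}, [TargetPrediction("m", "G2", 0.9, source="external")])
        assert net.edges == []

    def test_edge_set_equals_filter_join_oracle(self):
        rng = np.random.default_rng(3)
        hubs = {f"G{i}" for i in range(10)}
        preds = [
            TargetPrediction(f"m{rng.integers(5)}", f"G{rng.integers(20)}", 0.9,
                             source="external")
            for _ in range(40)
        ]
        net = build_bipartite(hubs, preds)
        expected = sorted({(p.mirna_id, p.gene_id) for p in preds if p.gene_id in hubs})
        assert sorted({(p.mirna_id, p.gene_id) for p in net.edges}) == expected


class TestExports:
    def test_graphml_and_sif_round_trip(self, tmp_path):
        from exomirnet.network import write_graphml, write_sif

        g = build_graph(_edges(("A", "B"), ("B", "C")), {"A", "B", "C", "Z"})
        write_graphml(g, tmp_path / "g.graphml", topology_scores(g))
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert set(back.nodes) == set(g.nodes)
        assert back.nodes["B"]["degree"] == 2
        write_sif(g, tmp_path / "g.sif")
        text = (tmp_path / "g.sif").read_text()
        assert "A\tpp\tB" in text and text.strip().endswith("Z")
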