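import networkx as nx
import numpy as np
import pytest

from _oracles import brute_betweenness, brute_clustering
from conftest import make_dag
from reposnet.io_formats import GeneAnnotations, InteractionList, PathwayCatalog
from reposnet.networks import (
    DiseaseNetwork,
    build_disease_network,
    build_hetero_network,
    build_hyperedges,
    build_weighted_disease_network,
    disease_gene_edge_weights,
    edge_weights,
    node_strengths,
    node_weights,
    pathway_score,
)
from reposnet.signatures import DrugTargetSet


def il(*pairs):
    return InteractionList(edges=set(pairs))


class TestBuildDiseaseNetwork:
    def test_external_interactions_filtered_isolated_kept(self):
        g = build_disease_network({"A", "B", "C"}, il(("A", "B"), ("A", "D")))
        assert set(g.nodes) == {"A", "B", "C"}
        assert set(map(frozenset, g.edges)) == {frozenset({"A", "B"})}
        assert g.degree("C") == 0

    def test_empty_interactions_give_edgeless_graph(self):
        g = build_disease_network({"A", "B"}, il())
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 2

    def test_internal_interactions_preserved(self):
        pairs = [("A", "B"), ("B", "C"), ("A", "C")]
        g = build_disease_network({"A", "B", "C"}, il(*pairs))
        assert g.number_of_edges() == 3

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            build_disease_network(set(), il())


class TestNodeWeights:
    def test_five_node_star(self):
        g = nx.star_graph(4)  # center 0
        w = node_weights(g)
        assert w[0].degree == 4 and w[0].betweenness == pytest.approx(6.0)
        assert w[0].weight == pytest.approx(2.0)  # clustering constant 0 -> contributes 0
        for leaf in range(1, 5):
            assert w[leaf].weight == 0.0

    def test_triangle_all_metrics_constant_all_weights_zero(self):
        g = nx.complete_graph(3)
        w = node_weights(g)
        assert all(m.weight == 0.0 for m in w.values())

    def test_path_graph_center(self):
        g = nx.path_graph(3)  # A-B-C
        w = node_weights(g)
        assert w[1].weight == pytest.approx(2.0)
        assert w[0].weight == 0.0 and w[2].weight == 0.0

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
            w = node_weights(g)
            bc = brute_betweenness(adj)
            cl = brute_clustering(adj)
            for i, n in enumerate(sorted(g.nodes)):
                assert w[n].betweenness == pytest.approx(bc[i], abs=1e-9)
                assert w[n].clustering == pytest.approx(cl[i], abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            node_weights(nx.Graph())


class TestEdgeWeights:
    def test_pathway_score_union_convention(self):
        cat = PathwayCatalog({"p1": {"u"}, "p2": {"u", "v"}, "p3": {"v"}})
        assert pathway_score("u", "v", cat) == pytest.approx(1 / 3)
        assert pathway_score("u", "v", cat, denominator="total") == pytest.approx(1 / 4)

    def test_no_pathways_scores_zero(self):
        cat = PathwayCatalog({})
        assert pathway_score("u", "v", cat) == 0.0

    def test_identical_features_give_weight_one(self):
        dag = make_dag([("t1", "root", "is_a")])
        anns = GeneAnnotations({"u": {"t1"}, "v": {"t1"}})
        cat = PathwayCatalog({"p": {"u", "v"}})
        g = nx.Graph([("u", "v")])
        edge_weights(g, anns, dag, cat)
        assert g.edges["u", "v"]["weight"] == pytest.approx(1.0)

    def test_missing_everything_gives_weight_zero(self):
        dag = make_dag([("t1", "root", "is_a")])
        g = nx.Graph([("u", "v")])
        edge_weights(g, GeneAnnotations({}), dag, PathwayCatalog({}))
        assert g.edges["u", "v"]["weight"] == 0.0
        assert g.edges["u", "v"]["go_sim"] == 0.0

    def test_sum_combiner(self):
        dag = make_dag([("t1", "root", "is_a")])
        anns = GeneAnnotations({"u": {"t1"}, "v": {"t1"}})
        cat = PathwayCatalog({"p": {"u", "v"}, "q": {"u"}})
        g = nx.Graph([("u", "v")])
        edge_weights(g, anns, dag, cat, combiner="sum")
        assert g.edges["u", "v"]["weight"] == pytest.approx(1.0 + 0.5)


class TestNodeStrengths:
    def test_strength_is_weight_plus_incident_edges(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b", weight=0.2)
        g.add_edge("a", "c", weight=0.3)
        for n, w in [("a", 0.5), ("b", 0.1), ("c", 0.0)]:
            g.nodes[n]["node_weight"] = w
        s = node_strengths(g)
        assert s["a"] == pytest.approx(1.0)
        assert s["b"] == pytest.approx(0.3)

    def test_isolated_node_strength_equals_weight(self):
        g = nx.Graph()
        g.add_node("x", node_weight=0.7)
        assert node_strengths(g)["x"] == pytest.approx(0.7)

    def test_zero_edge_weights_leave_strength_at_node_weight(self):
        g = nx.path_graph(4)
        node_weights(g)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = 0.0
        s = node_strengths(g)
        for n in g.nodes:
            assert s[n] == g.nodes[n]["node_weight"]


class TestDiseaseGeneEdgeWeights:
    def _network(self, weights: dict[str, float]) -> DiseaseNetwork:
        g = nx.Graph()
        for gene, w in weights.items():
            g.add_node(gene, node_weight=w, node_strength=w)
        return DiseaseNetwork(disease_id="d", graph=g)

    def test_top_and_bottom_of_ten(self):
        net = self._network({f"g{i:02d}": float(i) for i in range(10)})
        df = disease_gene_edge_weights(net).set_index("gene")
        assert df.loc["g09", "edge_weight"] == pytest.approx(0.9)
        assert df.loc["g09", "rank"] == 1
        assert df.loc["g00", "edge_weight"] == pytest.approx(0.0)

    def test_equal_weights_fall_back_to_lexicographic_tiebreak(self):
        net = self._network({"b": 1.0, "a": 1.0, "c": 1.0})
        df = disease_gene_edge_weights(net)
        assert df.gene.tolist() == ["a", "b", "c"]
        assert df.z.tolist() == [0.0, 0.0, 0.0]
        assert df.edge_weight.tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_weights_strictly_decrease_with_rank(self):
        net = self._network({f"g{i}": float(i % 4) for i in range(8)})
        df = disease_gene_edge_weights(net)
        assert (np.diff(df.edge_weight) < 0).all()

    def test_weight_sum_identity(self):
        rng = np.random.default_rng(5)
        for n in (1, 2, 7, 40):
            net = self._network({f"g{i}": float(rng.random()) for i in range(n)})
            df = disease_gene_edge_weights(net)
            assert df.edge_weight.sum() == pytest.approx((n - 1) / 2, abs=1e-9)

    def test_z_scores_standardized(self):
        net = self._network({f"g{i}": float(i) for i in range(5)})
        df = disease_gene_edge_weights(net)
        assert df.z.mean() == pytest.approx(0.0, abs=1e-12)
        assert df.z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)


def _mini_networks():
    """Two tiny disease networks with known node weights."""
    nets = {}
    for dis, genes in [("D1", ["g1", "g2", "g3"]), ("D2", ["g2", "g4"])]:
        g = nx.Graph()
        for i, gene in enumerate(genes):
            g.add_node(gene, node_weight=1.0 + i, node_strength=1.0 + i)
        nets[dis] = DiseaseNetwork(disease_id=dis, graph=g)
    return nets


class TestHeteroAndHyperedges:
    def test_drug_gene_edges_exist_iff_targeted(self):
        nets = _mini_networks()
        ts = [
            DrugTargetSet("D1", "rx", {"g1": ("up", "down")}),
            DrugTargetSet("D2", "rx", {"g4": ("down", "up")}),
            DrugTargetSet("D1", "ry", {}),
        ]
        h = build_hetero_network(nets, ts)
        assert h.graph.has_edge("drug::rx", "g1")
        assert h.graph.has_edge("drug::rx", "g4")
        assert not any(h.graph.has_edge("drug::ry", g) for g in ["g1", "g2", "g3", "g4"])
        assert h.graph.has_edge("disease::D1", "g1")
        # disease-gene weights in [0, 1)
        for dis in nets:
            for _, g, data in h.graph.edges(f"disease::{dis}", data=True):
                assert 0.0 <= data["weight"] < 1.0

    def test_refined_sets_follow_disease_links_and_opposite_regulation(self):
        nets = _mini_networks()
        ts = [
            DrugTargetSet("D1", "rx", {"g1": ("up", "down")}),
            # g4 belongs to D2 only; target set for D1 listing it has no effect
        ]
        h = build_hetero_network(nets, ts)
        hyper = build_hyperedges(h, ts)
        rx = next(e for e in hyper if e.drug_id == "rx")
        assert rx.genes == {"g1"}
        assert rx.refined == {"D1": {"g1"}, "D2": set()}

    def test_drug_with_no_targets_keeps_empty_hyperedge(self):
        nets = _mini_networks()
        ts = [DrugTargetSet("D1", "rz", {})]
        h = build_hetero_network(nets, ts)
        hyper = build_hyperedges(h, ts)
        rz = next(e for e in hyper if e.drug_id == "rz")
        assert rz.genes == set() and all(not s for s in rz.refined.values())

    def test_two_drugs_share_gene_pool_distinct_hyperedges(self):
        nets = _mini_networks()
        ts = [
            DrugTargetSet("D1", "letro", {"g1": ("up", "down"), "g2": ("up", "down")}),
            DrugTargetSet("D1", "dht", {"g2": ("up", "down"), "g3": ("down", "up")}),
        ]
        h = build_hetero_network(nets, ts)
        hyper = {e.drug_id: e for e in build_hyperedges(h, ts)}
        assert hyper["letro"].genes == {"g1", "g2"}
        assert hyper["dht"].genes == {"g2", "g3"}
        assert hyper["letro"].genes & hyper["dht"].genes == {"g2"}

    def test_shared_gene_has_per_disease_context_on_edges(self):
        nets = _mini_networks()
        h = build_hetero_network(nets, [])
        w1 = h.graph.edges["disease::D1", "g2"]["node_weight"]
        w2 = h.graph.edges["disease::D2", "g2"]["node_weight"]
        assert w1 == 2.0 and w2 == 1.0  # g2 is 2nd gene of D1, 1st of D2


def test_weighted_network_invariants_on_simulation_style_graph():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(25)]
    pairs = {
        (genes[a], genes[b])
        for a, b in {tuple(sorted(rng.choice(25, 2, replace=False))) for _ in range(40)}
    }
    net = build_weighted_disease_network("d", genes, InteractionList(edges=pairs))
    for gene, data in net.graph.nodes(data=True):
        assert 0.0 <= data["node_weight"] <= 3.0
        assert data["node_strength"] >= data["node_weight"] - 1e-12
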