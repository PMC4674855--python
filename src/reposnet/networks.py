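"""Weighted disease gene networks and the disease–gene–drug hypernetwork.

Two graphs are built. *Network I* is one simple undirected graph per
disease over its significant genes, with interactions kept only when
both endpoints are significant; genes with no surviving interaction stay
as isolated nodes. Each node gets

    node_weight = normalized(degree) + normalized(betweenness)
                  + normalized(clustering coefficient)

with min–max normalization across the network's nodes (a metric that is
constant across nodes contributes 0 for everyone), so node weights lie
in [0, 3]. Each edge gets

    edge_weight = combine(gene GO semantic similarity, pathway score)

where the pathway score is the overlap of the two genes' pathway
memberships (|common| / |union| by default) and the default combiner is
the arithmetic mean. Node strength is the node weight plus the sum of
incident edge weights, and ranks a disease's genes.

*Network II* adds one node per disease, connected to each of its
significant genes with weight

    weight(D, G) = 1 - rank(G) / N

where genes are ranked (rank 1 = highest) by the z-score of their node
weights within the disease and N is the disease's significant gene
count; ties break lexicographically so the construction is
deterministic. Drug nodes are then attached to the genes they oppositely
regulate, and each drug's gene neighbourhood together with the disease
nodes forms a hyperedge whose per-disease refined target sets drive the
scoring stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GeneAnnotations, GoDag, InteractionList, PathwayCatalog
from .semsim import gene_similarity
from .signatures import DrugTargetSet

__all__ = [
    "NodeMetrics",
    "DiseaseNetwork",
    "HeteroNetwork",
    "Hyperedge",
    "build_disease_network",
    "node_weights",
    "pathway_score",
    "edge_weights",
    "node_strengths",
    "build_weighted_disease_network",
    "disease_gene_edge_weights",
    "build_hetero_network",
    "build_hyperedges",
]


@dataclass(frozen=True)
class NodeMetrics:
    """Raw and min–max-normalized centrality metrics of one node."""

    degree: int
    betweenness: float
    clustering: float
    degree_norm: float
    betweenness_norm: float
    clustering_norm: float

    @property
    def weight(self) -> float:
        return self.degree_norm + self.betweenness_norm + self.clustering_norm


@dataclass
class DiseaseNetwork:
    """Per-disease weighted gene graph with node weights, edge weights and strengths."""

    disease_id: str
    graph: nx.Graph

    def node_weight(self, gene: str) -> float:
        return self.graph.nodes[gene]["node_weight"]

    def node_weights(self) -> dict[str, float]:
        return {g: d["node_weight"] for g, d in self.graph.nodes(data=True)}

    def total_node_weight(self) -> float:
        return float(sum(self.node_weights().values()))

    def node_strengths(self) -> dict[str, float]:
        return {g: d["node_strength"] for g, d in self.graph.nodes(data=True)}

    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    def ranked_genes(self) -> list[tuple[str, float]]:
        """Genes by node strength, descending; lexicographic tie-break."""
        strengths = self.node_strengths()
        return sorted(strengths.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class HeteroNetwork:
    """Disease + gene + drug nodes: gene–gene edges from Network I,
    disease–gene edges with the rank-based weight, drug–gene edges
    marking opposite regulation."""

    graph: nx.Graph
    diseases: list[str]
    drugs: list[str]
    gene_stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    #: per-disease DataFrame (gene, node_weight, z, rank, edge_weight)

    def disease_node(self, disease: str) -> str:
        return f"disease::{disease}"

    def drug_node(self, drug: str) -> str:
        return f"drug::{drug}"


@dataclass
class Hyperedge:
    """One drug's hyperedge: all its target gene nodes plus the disease nodes.

    ``refined`` maps disease → the genes of the hyperedge that are linked
    to that disease node *and* oppositely regulated by the drug for it.
    """

    drug_id: str
    genes: set[str]
    diseases: list[str]
    refined: dict[str, set[str]]


def build_disease_network(genes: Iterable[str], interactions: InteractionList) -> nx.Graph:
    """Simple undirected graph over the significant genes.

    Only interactions with both endpoints in the gene set are kept; genes
    with no surviving interaction remain as isolated nodes.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("gene set must be non-empty")
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    for a, b in interactions.edges:
        if a in genes and b in genes:
            g.add_edge(a, b)
    return g


def _min_max(values: dict[str, float]) -> dict[str, float]:
    lo, hi = min(values.values()), max(values.values())
    if math.isclose(lo, hi):
        return {k: 0.0 for k in values}
    span = hi - lo
    return {k: (v - lo) / span for k, v in values.items()}


def node_weights(graph: nx.Graph) -> dict[str, NodeMetrics]:
    """Centrality-based node weights; annotates the graph in place.

    Betweenness uses unweighted shortest paths on the undirected graph
    with endpoints excluded (the standard convention); clustering is the
    local clustering coefficient. Each metric is min–max normalized
    across nodes and the node weight is the sum of the three.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = {n: d for n, d in graph.degree()}
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    clustering = nx.clustering(graph)
    d_norm = _min_max({n: float(v) for n, v in degree.items()})
    b_norm = _min_max(betweenness)
    c_norm = _min_max(clustering)
    out: dict[str, NodeMetrics] = {}
    for n in graph.nodes:
        m = NodeMetrics(
            degree=degree[n],
            betweenness=betweenness[n],
            clustering=clustering[n],
            degree_norm=d_norm[n],
            betweenness_norm=b_norm[n],
            clustering_norm=c_norm[n],
        )
        out[n] = m
        graph.nodes[n].update(
            degree=m.degree,
            betweenness=m.betweenness,
            clustering=m.clustering,
            node_weight=m.weight,
        )
    return out


def pathway_score(
    gene_u: str, gene_v: str, pathways: PathwayCatalog, denominator: str = "union"
) -> float:
    """Overlap of two genes' pathway memberships, in [0, 1].

    ``denominator`` is ``union`` (|common| / |union|, the default) or
    ``total`` (|common| / (|P(u)| + |P(v)|)). Scores 0 when neither gene
    belongs to any pathway.
    """
    pu, pv = pathways.pathways_of(gene_u), pathways.pathways_of(gene_v)
    common = len(pu & pv)
    if denominator == "union":
        denom = len(pu | pv)
    elif denominator == "total":
        denom = len(pu) + len(pv)
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return common / denom if denom else 0.0


def edge_weights(
    graph: nx.Graph,
    anns: GeneAnnotations | None,
    dag: GoDag | None,
    pathways: PathwayCatalog | None,
    *,
    combiner: str = "mean",
    pathway_denominator: str = "union",
    namespace: str = "biological_process",
    combine: str = "bma",
    _sim_cache: dict | None = None,
) -> None:
    """Attach go_sim, pathway_score and weight attributes to every edge.

    A gene pair with undefined GO similarity (missing annotations)
    contributes 0 for that component rather than dropping the edge.
    ``combiner`` is ``mean`` (default) or ``sum`` of the two components.
    """
    if combiner not in ("mean", "sum"):
        raise ValueError(f"unknown combiner {combiner!r}")
    cache = _sim_cache if _sim_cache is not None else {}
    for u, v in graph.edges:
        if anns is not None and dag is not None:
            sim = gene_similarity(u, v, anns, dag, namespace=namespace, combine=combine, _cache=cache)
            go_sim = 0.0 if math.isnan(sim) else sim
        else:
            go_sim = 0.0
        pw = pathway_score(u, v, pathways, pathway_denominator) if pathways is not None else 0.0
        weight = (go_sim + pw) / 2.0 if combiner == "mean" else go_sim + pw
        graph.edges[u, v].update(go_sim=go_sim, pathway_score=pw, weight=weight)


def node_strengths(graph: nx.Graph) -> dict[str, float]:
    """node_strength = node_weight + sum of incident edge weights; in place."""
    out: dict[str, float] = {}
    for n in graph.nodes:
        s = graph.nodes[n]["node_weight"] + sum(
            graph.edges[n, nbr].get("weight", 0.0) for nbr in graph.neighbors(n)
        )
        graph.nodes[n]["node_strength"] = s
        out[n] = s
    return out


def build_weighted_disease_network(
    disease_id: str,
    genes: Iterable[str],
    interactions: InteractionList,
    anns: GeneAnnotations | None = None,
    dag: GoDag | None = None,
    pathways: PathwayCatalog | None = None,
    **edge_kwargs,
) -> DiseaseNetwork:
    """Convenience wrapper: build the graph and compute all weights."""
    g = build_disease_network(genes, interactions)
    node_weights(g)
    edge_weights(g, anns, dag, pathways, **edge_kwargs)
    node_strengths(g)
    return DiseaseNetwork(disease_id=disease_id, graph=g)


def disease_gene_edge_weights(network: DiseaseNetwork) -> pd.DataFrame:
    """Rank-based disease–gene edge weights for one disease.

    Node weights are z-scored across the disease's N significant genes
    (population SD; all z = 0 when the SD is 0), genes are ranked by z
    descending with a lexicographic tie-break, and the edge weight is
    1 − rank/N, so the top gene gets 1 − 1/N and the bottom gene 0.
    """
    weights = network.node_weights()
    n = len(weights)
    if n == 0:
        raise ValueError("disease network has no genes")
    values = np.array([weights[g] for g in sorted(weights)])
    sd = float(values.std())
    mean = float(values.mean())
    z = {g: ((weights[g] - mean) / sd if sd > 0 else 0.0) for g in weights}
    ordering = sorted(weights, key=lambda g: (-z[g], g))
    rows = [
        {
            "gene": g,
            "node_weight": weights[g],
            "z": z[g],
            "rank": i + 1,
            "edge_weight": 1.0 - (i + 1) / n,
        }
        for i, g in enumerate(ordering)
    ]
    return pd.DataFrame(rows)


def build_hetero_network(
    networks: Mapping[str, DiseaseNetwork],
    target_sets: Iterable[DrugTargetSet],
    *,
    compute_disease_node_weights: bool = False,
) -> HeteroNetwork:
    """Assemble Network II: union gene graph + disease nodes + drug nodes.

    Gene nodes are shared across diseases; each gene keeps one node
    weight *per disease context*, stored on the disease–gene edge
    together with the z, rank and rank-based weight. Drug–gene edges
    exist exactly for the genes of that drug's target sets.

    ``compute_disease_node_weights`` additionally computes the disease
    nodes' own centrality-based weights on the drug-free Network II (the
    same formula as for genes); these are exposed as node attributes but
    consumed by nothing downstream.
    """
    g = nx.Graph()
    diseases = sorted(networks)
    for dis in diseases:
        net = networks[dis]
        for gene, data in net.graph.nodes(data=True):
            g.add_node(gene, kind="gene")
        for u, v, data in net.graph.edges(data=True):
            g.add_edge(u, v, kind="gene-gene", **{k: data[k] for k in ("go_sim", "pathway_score", "weight") if k in data})

    gene_stats: dict[str, pd.DataFrame] = {}
    for dis in diseases:
        net = networks[dis]
        stats = disease_gene_edge_weights(net)
        gene_stats[dis] = stats
        dnode = f"disease::{dis}"
        g.add_node(dnode, kind="disease", disease=dis)
        for row in stats.itertuples(index=False):
            g.add_edge(
                dnode,
                row.gene,
                kind="disease-gene",
                weight=row.edge_weight,
                z=row.z,
                rank=row.rank,
                node_weight=row.node_weight,
            )

    if compute_disease_node_weights:
        node_weights(g)

    drugs: list[str] = []
    for ts in sorted(target_sets, key=lambda t: (t.drug_id, t.disease_id)):
        node = f"drug::{ts.drug_id}"
        if node not in g:
            g.add_node(node, kind="drug", drug=ts.drug_id)
            drugs.append(ts.drug_id)
        for gene, (d_dis, d_drug) in ts.targets.items():
            if g.has_edge(node, gene):
                data = g.edges[node, gene]
                data.setdefault("diseases", []).append(ts.disease_id)
            else:
                g.add_edge(node, gene, kind="drug-gene", diseases=[ts.disease_id])
    return HeteroNetwork(graph=g, diseases=diseases, drugs=drugs, gene_stats=gene_stats)


def build_hyperedges(
    hetero: HeteroNetwork, target_sets: Iterable[DrugTargetSet]
) -> list[Hyperedge]:
    """One hyperedge per drug: its gene neighbourhood plus all disease nodes.

    The per-disease refined target set keeps only the hyperedge genes
    that are adjacent to that disease's node *and* oppositely regulated
    by the drug for that disease. A drug with no target genes yields an
    empty hyperedge (kept; it scores 0 everywhere).
    """
    by_drug: dict[str, dict[str, set[str]]] = {}
    for ts in target_sets:
        by_drug.setdefault(ts.drug_id, {})[ts.disease_id] = ts.genes()
    out: list[Hyperedge] = []
    for drug in sorted(set(hetero.drugs) | set(by_drug)):
        node = hetero.drug_node(drug)
        genes = set(hetero.graph.neighbors(node)) if node in hetero.graph else set()
        refined: dict[str, set[str]] = {}
        for dis in hetero.diseases:
            dnode = hetero.disease_node(dis)
            linked = {g for g in genes if hetero.graph.has_edge(dnode, g)}
            refined[dis] = linked & by_drug.get(drug, {}).get(dis, set())
        out.append(Hyperedge(drug_id=drug, genes=genes, diseases=list(hetero.diseases), refined=refined))
    return out
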