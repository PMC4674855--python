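"""Synthetic input generator with planted disease signatures and reversing drugs.

Generates every input kind the pipeline consumes — expression studies,
gene–gene interactions, pathway memberships, a small GO DAG and gene
annotations — with known ground truth, so the full method is testable
without any downloads.

The statistical model mirrors what RMA-normalized microarray contrasts
look like after log2 transformation: each gene has a baseline intensity,
samples add i.i.d. Gaussian noise, and a planted disease gene shifts its
condition-group mean by ±``effect_size``. A "true" reversing drug shifts a
fraction of the planted genes in the *opposite* direction in its
post-treatment group (the signature-reversal hypothesis); decoy drugs
reverse few or none and instead perturb unrelated genes.

Everything is driven by a single :class:`numpy.random.Generator` seeded
from ``rng_seed``, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    GROUP_CONDITION,
    GROUP_REFERENCE,
    ExpressionStudy,
    GeneAnnotations,
    GoDag,
    InteractionList,
    PathwayCatalog,
    write_expression,
    write_gmt,
    write_interactions,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_study_pair",
    "simulate_support_data",
    "write_simulated_inputs",
]


@dataclass
class SimulationConfig:
    """Parameters of the simulated study panel.

    Defaults describe one disease with 50 planted genes out of a
    1000-gene universe (log2 effect ±2.0, noise SD 0.3, 5 samples per
    group) and a six-drug panel: the first drug reverses 80% of the
    planted genes, the remaining five are decoys reversing 10%.
    """

    n_genes: int = 1000
    n_samples_per_group: int = 5
    n_disease_genes: int = 50
    effect_size: float = 2.0
    noise_sd: float = 0.3
    reversal_fractions: tuple[float, ...] = (0.8, 0.1, 0.1, 0.1, 0.1, 0.1)
    decoy_perturbed_genes: int = 20
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    rng_seed: int = 0
    network_model: str = "preferential_attachment"  # or "erdos_renyi"
    pa_m: int = 2
    er_p: float = 0.01
    #: extra interaction probability among planted disease genes: disease
    #: genes form an enriched module in the interactome, the structural
    #: assumption the network stage relies on. 0.1 over 50 planted genes
    #: gives the module an average degree near 5, comparable to real
    #: disease networks.
    disease_module_p: float = 0.1
    n_pathways: int = 25
    pathway_size: tuple[int, int] = (10, 30)
    go_depth: int = 3
    go_branching: int = 3
    disease_name: str = "simulated_disease"

    @property
    def n_drugs(self) -> int:
        return len(self.reversal_fractions)

    def validate(self) -> None:
        if min(self.n_genes, self.n_samples_per_group, self.n_disease_genes) <= 0:
            raise ValueError("counts must be positive")
        if self.n_disease_genes > self.n_genes:
            raise ValueError("n_disease_genes exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for f in self.reversal_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError("reversal fractions must lie in [0, 1]")
        if self.network_model not in ("preferential_attachment", "erdos_renyi"):
            raise ValueError(f"unknown network model {self.network_model!r}")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def drug_names(self) -> list[str]:
        return [f"drug{d:02d}" for d in range(1, self.n_drugs + 1)]


@dataclass
class GroundTruth:
    """What was planted: disease genes with directions, and per-drug reversed sets."""

    disease_genes: dict[str, str]  # gene -> "up" | "down" (disease direction)
    reversed_by_drug: dict[str, set[str]]  # drug -> subset of disease_genes
    perturbed_by_drug: dict[str, dict[str, str]] = field(default_factory=dict)
    pathways: PathwayCatalog | None = None
    annotations: GeneAnnotations | None = None

    def __post_init__(self) -> None:
        planted = set(self.disease_genes)
        for drug, genes in self.reversed_by_drug.items():
            if not genes <= planted:
                raise ValueError(f"reversed set of {drug} is not a subset of planted disease genes")


def _two_group_matrix(
    baseline: np.ndarray,
    shift: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    prefix: str,
) -> ExpressionStudy:
    n = cfg.n_samples_per_group
    ref = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    cond = (baseline + shift)[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    samples = [f"{prefix}_ref{i+1}" for i in range(n)] + [f"{prefix}_cond{i+1}" for i in range(n)]
    matrix = pd.DataFrame(np.hstack([ref, cond]), index=cfg.gene_names(), columns=samples)
    groups = {s: (GROUP_REFERENCE if "_ref" in s else GROUP_CONDITION) for s in samples}
    return ExpressionStudy(matrix=matrix, groups=groups, study_id=prefix, condition_name=prefix)


def simulate_study_pair(
    cfg: SimulationConfig,
) -> tuple[ExpressionStudy, list[ExpressionStudy], GroundTruth]:
    """Simulate one disease study plus a panel of drug-treatment studies.

    The disease study shifts the planted genes by ±``effect_size``
    between groups; drug ``k`` shifts a fraction
    ``reversal_fractions[k]`` of the planted genes in the opposite
    direction, and decoy perturbations hit ``decoy_perturbed_genes``
    non-disease genes per drug. Fully deterministic given ``rng_seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    genes = cfg.gene_names()
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    planted_idx = rng.choice(cfg.n_genes, size=cfg.n_disease_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_disease_genes)
    disease_shift = np.zeros(cfg.n_genes)
    disease_shift[planted_idx] = signs * cfg.effect_size
    disease_genes = {
        genes[i]: ("up" if s > 0 else "down") for i, s in zip(planted_idx, signs)
    }
    disease = _two_group_matrix(baseline, disease_shift, cfg, rng, cfg.disease_name)

    other_idx = np.setdiff1d(np.arange(cfg.n_genes), planted_idx)
    drugs: list[ExpressionStudy] = []
    reversed_by_drug: dict[str, set[str]] = {}
    perturbed_by_drug: dict[str, dict[str, str]] = {}
    for drug, frac in zip(cfg.drug_names(), cfg.reversal_fractions):
        n_rev = int(round(frac * cfg.n_disease_genes))
        rev_idx = rng.choice(planted_idx, size=n_rev, replace=False) if n_rev else np.array([], dtype=int)
        drug_shift = np.zeros(cfg.n_genes)
        drug_shift[rev_idx] = -disease_shift[rev_idx]
        n_decoy = min(cfg.decoy_perturbed_genes, other_idx.size)
        decoy_idx = rng.choice(other_idx, size=n_decoy, replace=False) if n_decoy else np.array([], dtype=int)
        decoy_signs = rng.choice([-1.0, 1.0], size=decoy_idx.size)
        drug_shift[decoy_idx] = decoy_signs * cfg.effect_size
        study = _two_group_matrix(baseline, drug_shift, cfg, rng, drug)
        drugs.append(study)
        reversed_by_drug[drug] = {genes[i] for i in rev_idx}
        perturbed = {genes[i]: ("up" if drug_shift[i] > 0 else "down") for i in rev_idx}
        perturbed.update({genes[i]: ("up" if s > 0 else "down") for i, s in zip(decoy_idx, decoy_signs)})
        perturbed_by_drug[drug] = perturbed

    truth = GroundTruth(
        disease_genes=disease_genes,
        reversed_by_drug=reversed_by_drug,
        perturbed_by_drug=perturbed_by_drug,
    )
    return disease, drugs, truth


def _preferential_attachment_edges(n: int, m: int, rng: np.random.Generator) -> set[tuple[int, int]]:
    """Growing network: a 3-node seed triangle, then m distinct degree-
    proportional attachments per new node."""
    if n < 3:
        raise ValueError("preferential attachment needs n >= 3")
    edges = {(0, 1), (0, 2), (1, 2)}
    # repeated-node list: node appears once per incident edge end
    stubs = [0, 0, 1, 1, 2, 2]
    for new in range(3, n):
        targets: set[int] = set()
        k = min(m, new)
        while len(targets) < k:
            targets.add(stubs[rng.integers(len(stubs))])
        for t in sorted(targets):
            edges.add((t, new))
            stubs.extend([t, new])
    return edges


def simulate_support_data(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[InteractionList, PathwayCatalog, GoDag, GeneAnnotations]:
    """Generate interactions, pathways, a layered GO DAG and annotations.

    The interaction network comes from the configured random-graph model
    over the whole gene universe. Pathways are blocks seeded on a random
    gene and filled from its network neighbourhood (so pathway comembers
    tend to interact). The GO DAG is a small layered tree-with-shortcuts;
    genes are annotated to leaf terms, with genes of one pathway sharing
    that pathway's "home" leaves. Results are stored back onto ``truth``.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, 1)))
    genes = cfg.gene_names()

    if cfg.network_model == "preferential_attachment":
        int_edges = _preferential_attachment_edges(cfg.n_genes, cfg.pa_m, rng)
    else:
        g = nx.gnp_random_graph(cfg.n_genes, cfg.er_p, seed=int(rng.integers(2**31)))
        int_edges = {(min(u, v), max(u, v)) for u, v in g.edges}
    # disease-module enrichment: planted disease genes interact with each
    # other above background, as disease genes do in real interactomes
    name_to_idx = {g: i for i, g in enumerate(genes)}
    planted = sorted(name_to_idx[g] for g in truth.disease_genes)
    for i, a in enumerate(planted):
        for b in planted[i + 1 :]:
            if rng.random() < cfg.disease_module_p:
                int_edges.add((a, b))
    interactions = InteractionList(
        edges={(genes[a], genes[b]) for a, b in int_edges}, source="simulated"
    )
    graph = nx.Graph()
    graph.add_nodes_from(range(cfg.n_genes))
    graph.add_edges_from(int_edges)

    lo, hi = cfg.pathway_size
    pathways: dict[str, set[str]] = {}
    for p in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        seed_gene = int(rng.integers(cfg.n_genes))
        # grow from the seed's neighbourhood, then pad with random genes
        members = [seed_gene]
        frontier = sorted(graph.neighbors(seed_gene))
        while frontier and len(members) < size:
            nxt = frontier.pop(int(rng.integers(len(frontier))))
            if nxt not in members:
                members.append(nxt)
                frontier.extend(g2 for g2 in sorted(graph.neighbors(nxt)) if g2 not in members)
        while len(members) < size:
            cand = int(rng.integers(cfg.n_genes))
            if cand not in members:
                members.append(cand)
        pathways[f"PW{p+1:03d}"] = {genes[i] for i in members}
    catalog = PathwayCatalog(pathways)

    dag, leaves = _layered_go_dag(cfg.go_depth, cfg.go_branching, rng)
    home_leaf = {pw: leaves[int(rng.integers(len(leaves)))] for pw in sorted(pathways)}
    ann: dict[str, set[str]] = {}
    for gene in genes:
        terms = {home_leaf[pw] for pw in sorted(catalog.pathways_of(gene))}
        n_extra = int(rng.integers(1, 3))
        terms |= {leaves[int(rng.integers(len(leaves)))] for _ in range(n_extra)}
        ann[gene] = terms
    annotations = GeneAnnotations(ann)

    truth.pathways = catalog
    truth.annotations = annotations
    return interactions, catalog, dag, annotations


def _layered_go_dag(depth: int, branching: int, rng: np.random.Generator) -> tuple[GoDag, list[str]]:
    """A rooted layered DAG: each term has one is_a parent in the layer
    above, plus an occasional extra part_of parent."""
    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    root = "GO:SIM0000"
    graph.add_node(root)
    namespace[root] = "biological_process"
    counter = 1
    layers = [[root]]
    for _ in range(depth):
        prev = layers[-1]
        layer = []
        for parent in prev:
            for _ in range(branching):
                term = f"GO:SIM{counter:04d}"
                counter += 1
                graph.add_node(term)
                namespace[term] = "biological_process"
                graph.add_edge(term, parent, relation="is_a")
                if len(prev) > 1 and rng.random() < 0.15:
                    extra = prev[int(rng.integers(len(prev)))]
                    if extra != parent:
                        graph.add_edge(term, extra, relation="part_of")
                layer.append(term)
        layers.append(layer)
    return GoDag(graph=graph, namespace=namespace), layers[-1]


def write_simulated_inputs(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write all simulated inputs as pipeline-ready files plus a ground-truth TSV.

    Returns a mapping of logical names to paths (``disease_matrix``,
    ``disease_groups``, ``drugXX_matrix`` …, ``interactions``, ``gmt``,
    ``obo``, ``annotations``, ``truth``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    disease, drugs, truth = simulate_study_pair(cfg)
    interactions, catalog, dag, annotations = simulate_support_data(cfg, truth)

    paths: dict[str, Path] = {}

    def _expr(study: ExpressionStudy, stem: str) -> None:
        m, g = out / f"{stem}_matrix.tsv", out / f"{stem}_groups.tsv"
        write_expression(study, m, g)
        paths[f"{stem}_matrix"] = m
        paths[f"{stem}_groups"] = g

    _expr(disease, "disease")
    for study in drugs:
        _expr(study, study.study_id)

    paths["interactions"] = out / "interactions.tsv"
    write_interactions(interactions, paths["interactions"])
    paths["gmt"] = out / "pathways.gmt"
    write_gmt(catalog, paths["gmt"])
    paths["obo"] = out / "ontology.obo"
    _write_obo(dag, paths["obo"])
    paths["annotations"] = out / "annotations.tsv"
    with open(paths["annotations"], "w") as fh:
        for gene in sorted(annotations.mapping):
            for term in sorted(annotations.mapping[gene]):
                fh.write(f"{gene}\t{term}\n")
    paths["truth"] = out / "ground_truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("gene\tdisease_direction\treversing_drugs\n")
        for gene in sorted(truth.disease_genes):
            drugs_hit = sorted(d for d, s in truth.reversed_by_drug.items() if gene in s)
            fh.write(f"{gene}\t{truth.disease_genes[gene]}\t{','.join(drugs_hit)}\n")
    return paths


def _write_obo(dag: GoDag, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: simulated\n")
        for term in sorted(dag.graph.nodes):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            fh.write(f"namespace: {dag.namespace.get(term, 'biological_process')}\n")
            for parent, rel in sorted(dag.parents(term)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
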