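"""End-to-end orchestration: signatures → targets → networks → scores.

The six stages are:

1. differential expression per disease dataset (Set A candidates);
2. differential expression per drug dataset, with timepoints of one
   dosage intersected (Set B); multiple dosages stay separate drugs;
3. signature reversal: per (disease, drug), the common genes with
   opposite regulation; optionally restrict each disease's gene set to
   genes targeted by at least one drug before network construction;
4. a weighted gene network per disease (centrality node weights, GO +
   pathway edge weights, node strengths);
5. the heterogeneous network adding disease nodes (rank-based
   disease–gene edge weights) and drug nodes;
6. hyperedge extraction and disease–gene–drug / disease–drug scoring.

:func:`run_core` does all of this on in-memory domain objects and is the
single code path used by the file-driven pipeline, the simulation
harness and the tests. :func:`run_pipeline` wraps it with config
parsing, file loading and TSV/GraphML report writing. Outputs carry no
timestamps, so identical config + seed reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import pandas as pd
import yaml

from . import diffexpr, io_formats, networks, scoring, signatures
from .diffexpr import ContrastResult, GeneSignature
from .io_formats import (
    ExpressionStudy,
    GeneAnnotations,
    GoDag,
    InteractionList,
    PathwayCatalog,
)
from .networks import DiseaseNetwork, HeteroNetwork, Hyperedge
from .signatures import DrugTargetSet

__all__ = [
    "PipelineOptions",
    "PipelineData",
    "PipelineResult",
    "PipelineConfig",
    "run_core",
    "run_pipeline",
    "load_config",
    "write_outputs",
]

CANCEROUS = "cancerous"
NON_CANCEROUS = "non_cancerous"


@dataclass
class PipelineOptions:
    """Every method convention the pipeline leaves configurable.

    The FDR thresholds default to 0.01 for the ``cancerous`` disease
    class and 0.05 for ``non_cancerous``; the Step-2/3 restriction of
    disease genes to drug-affected ones is on by default; the edge-weight
    combiner, pathway-score denominator, GO namespace, gene-similarity
    combination and DE method carry the defaults documented in their
    modules.
    """

    q_thresholds: dict[str, float] = field(
        default_factory=lambda: {CANCEROUS: 0.01, NON_CANCEROUS: 0.05}
    )
    de_method: str = "moderated"
    step2_restriction: bool = True
    edge_combiner: str = "mean"
    pathway_denominator_rule: str = "union"
    go_namespace: str = "biological_process"
    gene_sim_combine: str = "bma"
    min_interaction_floor: int = 10
    top_k_genes: int = 10

    def q_for(self, disease_class: str) -> float:
        try:
            return self.q_thresholds[disease_class]
        except KeyError:
            raise ValueError(f"no q threshold configured for class {disease_class!r}")


@dataclass
class PipelineData:
    """In-memory pipeline inputs, already collapsed to gene symbols."""

    disease_studies: dict[str, list[ExpressionStudy]]
    drug_studies: dict[str, list[ExpressionStudy]]  # timepoints of one dosage
    interactions: InteractionList
    disease_class: dict[str, str] = field(default_factory=dict)
    drug_class: dict[str, str] = field(default_factory=dict)
    pathways: PathwayCatalog | None = None
    dag: GoDag | None = None
    annotations: GeneAnnotations | None = None

    def class_of_disease(self, disease: str) -> str:
        return self.disease_class.get(disease, CANCEROUS)

    def class_of_drug(self, drug: str) -> str:
        return self.drug_class.get(drug, CANCEROUS)


@dataclass
class PipelineResult:
    contrasts: dict[str, ContrastResult]
    disease_signatures: dict[str, GeneSignature]
    drug_signatures: dict[str, GeneSignature]
    target_sets: list[DrugTargetSet]
    network_genes: dict[str, set[str]]  # genes actually carried into each network
    networks: dict[str, DiseaseNetwork]
    hetero: HeteroNetwork
    hyperedges: list[Hyperedge]
    triple_scores: list[scoring.TripleScore]
    pair_matrix: pd.DataFrame
    rankings: dict[str, pd.DataFrame]
    manifest: dict[str, Any]
    log: list[str]


def run_core(data: PipelineData, options: PipelineOptions | None = None) -> PipelineResult:
    """Run stages 1–6 on in-memory inputs."""
    opt = options or PipelineOptions()
    log: list[str] = []
    contrasts: dict[str, ContrastResult] = {}

    disease_signatures: dict[str, GeneSignature] = {}
    for disease in sorted(data.disease_studies):
        q = opt.q_for(data.class_of_disease(disease))
        results = []
        for study in data.disease_studies[disease]:
            res = diffexpr.differential_expression(study, q_threshold=q, method=opt.de_method)
            contrasts[res.study_id] = res
            results.append(res)
            log.append(f"deg\t{res.study_id}\tsignificant={int(res.table.significant.sum())}")
        sig = diffexpr.combine_disease_datasets(results, label=disease)
        disease_signatures[disease] = sig
        for gene in sorted(sig.conflicting):
            log.append(f"conflict\t{disease}\t{gene}\tdirection-disagreement-across-datasets")

    drug_signatures: dict[str, GeneSignature] = {}
    for drug in sorted(data.drug_studies):
        q = opt.q_for(data.class_of_drug(drug))
        results = []
        for study in data.drug_studies[drug]:
            res = diffexpr.differential_expression(study, q_threshold=q, method=opt.de_method)
            contrasts[res.study_id] = res
            results.append(res)
            log.append(f"deg\t{res.study_id}\tsignificant={int(res.table.significant.sum())}")
        sig = diffexpr.combine_drug_timepoints(results, label=drug)
        drug_signatures[drug] = sig
        for gene in sorted(sig.conflicting):
            log.append(f"conflict\t{drug}\t{gene}\tdirection-disagreement-across-timepoints")

    target_sets: list[DrugTargetSet] = []
    for disease in sorted(disease_signatures):
        for drug in sorted(drug_signatures):
            ts = signatures.opposite_regulation(
                disease_signatures[disease].directions,
                drug_signatures[drug].directions,
                disease_id=disease,
                drug_id=drug,
            )
            target_sets.append(ts)
            log.append(f"targets\t{disease}\t{drug}\tn={len(ts)}")

    network_genes: dict[str, set[str]] = {}
    nets: dict[str, DiseaseNetwork] = {}
    sim_cache: dict = {}
    for disease in sorted(disease_signatures):
        genes = disease_signatures[disease].genes()
        if opt.step2_restriction:
            genes = signatures.restrict_to_drug_affected(
                genes, [ts for ts in target_sets if ts.disease_id == disease]
            )
            log.append(f"step2-restriction\t{disease}\tkept={len(genes)}")
        network_genes[disease] = genes
        if not genes:
            log.append(f"network\t{disease}\tSKIPPED-no-genes")
            continue
        net = networks.build_weighted_disease_network(
            disease,
            genes,
            data.interactions,
            data.annotations,
            data.dag,
            data.pathways,
            combiner=opt.edge_combiner,
            pathway_denominator=opt.pathway_denominator_rule,
            namespace=opt.go_namespace,
            combine=opt.gene_sim_combine,
            _sim_cache=sim_cache,
        )
        nets[disease] = net
        n_edges = net.graph.number_of_edges()
        log.append(f"network\t{disease}\tgenes={len(genes)}\tinteractions={n_edges}")
        if n_edges < opt.min_interaction_floor:
            log.append(
                f"flag\t{disease}\tonly {n_edges} interactions "
                f"(< floor {opt.min_interaction_floor}); consider dropping this disease"
            )

    scored_targets = [ts for ts in target_sets if ts.disease_id in nets]
    hetero = networks.build_hetero_network(nets, scored_targets)
    hyperedges = networks.build_hyperedges(hetero, scored_targets)
    triple_scores: list[scoring.TripleScore] = []
    for hyper in hyperedges:
        triple_scores.extend(scoring.score_triples(hyper, nets))
    pair_matrix = scoring.pair_score_matrix(hyperedges, nets)
    rankings = scoring.rank_candidates(hyperedges, nets, top_k_genes=opt.top_k_genes)

    manifest = _build_manifest(
        contrasts, disease_signatures, drug_signatures, target_sets, network_genes, nets, hyperedges
    )
    return PipelineResult(
        contrasts=contrasts,
        disease_signatures=disease_signatures,
        drug_signatures=drug_signatures,
        target_sets=target_sets,
        network_genes=network_genes,
        networks=nets,
        hetero=hetero,
        hyperedges=hyperedges,
        triple_scores=triple_scores,
        pair_matrix=pair_matrix,
        rankings=rankings,
        manifest=manifest,
        log=log,
    )


def _build_manifest(contrasts, disease_sigs, drug_sigs, target_sets, network_genes, nets, hyperedges):
    per_contrast = {
        sid: int(res.table.significant.sum()) for sid, res in sorted(contrasts.items())
    }
    per_disease = {}
    for dis in sorted(disease_sigs):
        net = nets.get(dis)
        per_disease[dis] = {
            "significant_genes": len(disease_sigs[dis].directions),
            "conflicting_genes": len(disease_sigs[dis].conflicting),
            "network_genes": len(network_genes.get(dis, set())),
            "interactions": net.graph.number_of_edges() if net else 0,
        }
    per_drug = {}
    for drug in sorted(drug_sigs):
        refined = {}
        for h in hyperedges:
            if h.drug_id == drug:
                refined = {d: len(g) for d, g in sorted(h.refined.items())}
        per_drug[drug] = {
            "significant_genes": len(drug_sigs[drug].directions),
            "targets_per_disease": {
                ts.disease_id: len(ts) for ts in target_sets if ts.drug_id == drug
            },
            "refined_targets_per_disease": refined,
        }
    return {
        "significant_genes_per_contrast": per_contrast,
        "diseases": per_disease,
        "drugs": per_drug,
    }


# ---------------------------------------------------------------------------
# file-driven configuration


@dataclass
class DatasetConfig:
    matrix: Path
    groups: Path
    annotation: Path | None = None
    study_id: str = ""
    timepoint: str | None = None


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (see :func:`load_config` for the YAML)."""

    out_dir: Path
    interactions: Path
    diseases: dict[str, list[DatasetConfig]]
    drugs: dict[str, list[DatasetConfig]]
    disease_class: dict[str, str]
    drug_class: dict[str, str]
    gmt: Path | None = None
    obo: Path | None = None
    annotations: Path | None = None
    options: PipelineOptions = field(default_factory=PipelineOptions)
    seed: int = 0
    raw: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check every referenced input file exists before any computation."""
        missing: list[str] = []

        def _check(p: Path | None, what: str) -> None:
            if p is not None and not Path(p).is_file():
                missing.append(f"{what}: {p}")

        _check(self.interactions, "interactions")
        _check(self.gmt, "gmt")
        _check(self.obo, "obo")
        _check(self.annotations, "annotations")
        for name, dsets in list(self.diseases.items()) + list(self.drugs.items()):
            for ds in dsets:
                _check(ds.matrix, f"{name} matrix")
                _check(ds.groups, f"{name} groups")
                _check(ds.annotation, f"{name} annotation")
        if missing:
            raise FileNotFoundError("missing input files:\n  " + "\n  ".join(missing))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config.

    Layout::

        out_dir: out/
        seed: 1
        interactions: interactions.tsv
        gmt: pathways.gmt          # optional
        obo: ontology.obo          # optional
        annotations: annotations.tsv  # optional (GAF or 2-column TSV)
        options: {step2_restriction: true, edge_combiner: mean, ...}
        diseases:
          lung_cancer:
            class: cancerous
            datasets:
              - {matrix: m.tsv, groups: g.tsv, annotation: probes.tsv}
        drugs:
          letrozole:
            class: cancerous
            timepoints:
              - {matrix: m.tsv, groups: g.tsv, timepoint: 12h}
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def _p(v: str | None) -> Path | None:
        return None if v is None else (base / v if not Path(v).is_absolute() else Path(v))

    def _datasets(entries: list[dict], owner: str) -> list[DatasetConfig]:
        out = []
        for i, e in enumerate(entries):
            out.append(
                DatasetConfig(
                    matrix=_p(e["matrix"]),
                    groups=_p(e["groups"]),
                    annotation=_p(e.get("annotation")),
                    study_id=e.get("study_id", f"{owner}_{i+1}"),
                    timepoint=e.get("timepoint"),
                )
            )
        return out

    diseases: dict[str, list[DatasetConfig]] = {}
    disease_class: dict[str, str] = {}
    for name, spec in (raw.get("diseases") or {}).items():
        diseases[name] = _datasets(spec.get("datasets", []), name)
        disease_class[name] = spec.get("class", CANCEROUS)
    drugs: dict[str, list[DatasetConfig]] = {}
    drug_class: dict[str, str] = {}
    for name, spec in (raw.get("drugs") or {}).items():
        drugs[name] = _datasets(spec.get("timepoints", spec.get("datasets", [])), name)
        drug_class[name] = spec.get("class", CANCEROUS)

    opt_kwargs = dict(raw.get("options") or {})
    if "q_thresholds" in opt_kwargs:
        opt_kwargs["q_thresholds"] = dict(opt_kwargs["q_thresholds"])
    options = PipelineOptions(**opt_kwargs)
    return PipelineConfig(
        out_dir=_p(raw["out_dir"]),
        interactions=_p(raw["interactions"]),
        diseases=diseases,
        drugs=drugs,
        disease_class=disease_class,
        drug_class=drug_class,
        gmt=_p(raw.get("gmt")),
        obo=_p(raw.get("obo")),
        annotations=_p(raw.get("annotations")),
        options=options,
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )


def _load_study(ds: DatasetConfig, condition: str) -> ExpressionStudy:
    study = io_formats.read_expression(
        ds.matrix, ds.groups, study_id=ds.study_id, condition_name=condition, timepoint=ds.timepoint
    )
    if ds.annotation is not None:
        ann = io_formats.read_probe_annotation(ds.annotation)
        study = diffexpr.collapse_probes(study, ann)
    return study


def run_pipeline(config: PipelineConfig | str | Path) -> PipelineResult:
    """Load all inputs per the config, run the six stages, write the report."""
    cfg = load_config(config) if not isinstance(config, PipelineConfig) else config
    cfg.validate()

    interactions = io_formats.read_interactions(cfg.interactions)
    pathways = io_formats.read_gmt(cfg.gmt) if cfg.gmt else None
    dag = io_formats.read_obo(cfg.obo) if cfg.obo else None
    anns = io_formats.read_gaf(cfg.annotations, dag) if (cfg.annotations and dag) else None

    data = PipelineData(
        disease_studies={
            d: [_load_study(ds, d) for ds in dsets] for d, dsets in sorted(cfg.diseases.items())
        },
        drug_studies={
            d: [_load_study(ds, d) for ds in dsets] for d, dsets in sorted(cfg.drugs.items())
        },
        interactions=interactions,
        disease_class=cfg.disease_class,
        drug_class=cfg.drug_class,
        pathways=pathways,
        dag=dag,
        annotations=anns,
    )
    result = run_core(data, cfg.options)
    write_outputs(result, cfg.out_dir, config_hash=cfg.config_hash())
    return result


def _graphml_safe(graph: nx.Graph) -> nx.Graph:
    """Copy with non-scalar attributes stringified, nodes/edges sorted."""
    g = nx.Graph()
    for n in sorted(graph.nodes, key=str):
        g.add_node(n, **{k: (",".join(map(str, v)) if isinstance(v, (list, set, tuple)) else v)
                         for k, v in sorted(graph.nodes[n].items())})
    for u, v in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
        g.add_edge(u, v, **{k: (",".join(map(str, w)) if isinstance(w, (list, set, tuple)) else w)
                            for k, w in sorted(graph.edges[u, v].items())})
    return g


def write_outputs(result: PipelineResult, out_dir: str | Path, config_hash: str = "") -> None:
    """Write per-stage TSVs, GraphML networks, rankings, manifest and log."""
    out = Path(out_dir)
    for sub in ("contrasts", "signatures", "networks", "scores"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    for sid, res in sorted(result.contrasts.items()):
        tbl = res.table.copy()
        tbl["direction"] = tbl["direction"].fillna("")
        tbl.to_csv(out / "contrasts" / f"{sid}.tsv", sep="\t", index=False, float_format="%.10g")

    for kind, sigs in (("disease", result.disease_signatures), ("drug", result.drug_signatures)):
        for name, sig in sorted(sigs.items()):
            rows = [
                {"gene": g, "direction": d, "datasets": ",".join(sig.provenance.get(g, []))}
                for g, d in sorted(sig.directions.items())
            ] + [{"gene": g, "direction": "conflicting", "datasets": ""} for g in sorted(sig.conflicting)]
            pd.DataFrame(rows, columns=["gene", "direction", "datasets"]).to_csv(
                out / "signatures" / f"{kind}_{name}.tsv", sep="\t", index=False
            )

    target_rows = [
        {
            "disease": ts.disease_id,
            "drug": ts.drug_id,
            "gene": g,
            "disease_direction": dd,
            "drug_direction": rd,
        }
        for ts in sorted(result.target_sets, key=lambda t: (t.disease_id, t.drug_id))
        for g, (dd, rd) in sorted(ts.targets.items())
    ]
    pd.DataFrame(
        target_rows, columns=["disease", "drug", "gene", "disease_direction", "drug_direction"]
    ).to_csv(out / "targets.tsv", sep="\t", index=False)

    for dis, net in sorted(result.networks.items()):
        nx.write_graphml(_graphml_safe(net.graph), out / "networks" / f"{dis}.graphml")
        io_formats.write_edge_list(net.graph, out / "networks" / f"{dis}_edges.tsv")
        ranked = net.ranked_genes()
        pd.DataFrame(
            [
                {
                    "gene": g,
                    "node_strength": s,
                    "node_weight": net.node_weight(g),
                    "rank": i + 1,
                }
                for i, (g, s) in enumerate(ranked)
            ]
        ).to_csv(out / "networks" / f"{dis}_gene_ranking.tsv", sep="\t", index=False, float_format="%.10g")

    nx.write_graphml(_graphml_safe(result.hetero.graph), out / "networks" / "hetero.graphml")

    pd.DataFrame(
        [
            {
                "disease": t.disease,
                "gene": t.gene,
                "drug": t.drug,
                "P": t.P,
                "Q": t.Q,
                "S": t.S,
                "score": t.score,
            }
            for t in result.triple_scores
        ],
        columns=["disease", "gene", "drug", "P", "Q", "S", "score"],
    ).to_csv(out / "scores" / "triple_scores.tsv", sep="\t", index=False, float_format="%.10g")
    result.pair_matrix.to_csv(out / "scores" / "disease_drug_scores.tsv", sep="\t", float_format="%.10g")
    for dis, df in sorted(result.rankings.items()):
        df.to_csv(out / "scores" / f"ranking_{dis}.tsv", sep="\t", index=False, float_format="%.10g")

    manifest = dict(result.manifest)
    manifest["config_hash"] = config_hash
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "log.txt", "w") as fh:
        fh.write("\n".join(result.log) + "\n")
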