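"""Disease–gene–drug and disease–drug scoring over the hypernetwork.

For a drug Dr whose hyperedge refines to S target genes for disease Ds,
each targeted gene G is scored by

    score(Ds, G, Dr) = A * B,   A = P / Q,   B = 1 / S

where P is G's node weight in Ds's network and Q the total node weight
of all Ds genes — A is the gene's relative contribution to the disease,
B the drug's (assumed equal) per-target effect. The disease–drug pair is
scored by

    score(Ds, Dr) = Y / Z

with Y the summed node weights of the Ds genes the drug targets and Z
the summed node weights of all Ds genes: the fraction of the disease
network's weight the drug reverses, in [0, 1]. The two are linked by the
exact identity sum_G score(Ds, G, Dr) = score(Ds, Dr) / S.

A high pair score means the drug touches a large share of the disease
network; a low-scoring drug can still be interesting when its few
targets are high-strength hub genes, so rankings list the top target
genes by node strength alongside each pair score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .networks import DiseaseNetwork, Hyperedge

__all__ = [
    "TripleScore",
    "DiseaseDrugScore",
    "score_triples",
    "score_pairs",
    "pair_score_matrix",
    "rank_candidates",
]


@dataclass(frozen=True)
class TripleScore:
    """Score of one (disease, gene, drug) connection."""

    disease: str
    gene: str
    drug: str
    P: float
    Q: float
    S: int
    score: float
    degenerate: bool = False  # Q == 0: A undefined, score forced to 0

    @property
    def A(self) -> float:
        return self.P / self.Q if self.Q > 0 else float("nan")

    @property
    def B(self) -> float:
        return 1.0 / self.S


@dataclass(frozen=True)
class DiseaseDrugScore:
    """Score of one (disease, drug) connection: the Y/Z weight fraction."""

    disease: str
    drug: str
    Y: float
    Z: float
    score: float
    n_targets: int
    degenerate: bool = False  # Z == 0


def score_triples(
    hyper: Hyperedge, networks: Mapping[str, DiseaseNetwork]
) -> list[TripleScore]:
    """One TripleScore per (disease, refined target gene) of the hyperedge.

    Sorted descending by score with a deterministic (disease, gene)
    tie-break. When a disease's total node weight Q is 0 the triples are
    still reported, flagged degenerate with score 0.
    """
    out: list[TripleScore] = []
    for dis in hyper.diseases:
        targets = sorted(hyper.refined.get(dis, set()))
        if not targets:
            continue
        net = networks[dis]
        q = net.total_node_weight()
        s = len(targets)
        for gene in targets:
            p = net.node_weight(gene)
            if q > 0:
                out.append(TripleScore(dis, gene, hyper.drug_id, p, q, s, (p / q) * (1.0 / s)))
            else:
                out.append(TripleScore(dis, gene, hyper.drug_id, p, q, s, 0.0, degenerate=True))
    out.sort(key=lambda t: (-t.score, t.disease, t.gene))
    return out


def score_pairs(
    hyper: Hyperedge, networks: Mapping[str, DiseaseNetwork]
) -> list[DiseaseDrugScore]:
    """The drug's pair score against every disease in the hyperedge."""
    out: list[DiseaseDrugScore] = []
    for dis in hyper.diseases:
        net = networks[dis]
        targets = sorted(hyper.refined.get(dis, set()))
        z = net.total_node_weight()
        y = float(sum(net.node_weight(g) for g in targets))
        if z > 0:
            out.append(DiseaseDrugScore(dis, hyper.drug_id, y, z, y / z, len(targets)))
        else:
            out.append(DiseaseDrugScore(dis, hyper.drug_id, y, z, 0.0, len(targets), degenerate=True))
    return out


def pair_score_matrix(
    hyperedges: Iterable[Hyperedge], networks: Mapping[str, DiseaseNetwork]
) -> pd.DataFrame:
    """Full drug × disease score matrix (drugs as rows, diseases as columns)."""
    rows: dict[str, dict[str, float]] = {}
    diseases: list[str] = []
    for hyper in hyperedges:
        for sc in score_pairs(hyper, networks):
            rows.setdefault(sc.drug, {})[sc.disease] = sc.score
            if sc.disease not in diseases:
                diseases.append(sc.disease)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(sorted(df.index))[sorted(diseases)] if not df.empty else df
    df.index.name = "drug"
    return df


def rank_candidates(
    hyperedges: Iterable[Hyperedge],
    networks: Mapping[str, DiseaseNetwork],
    top_k_genes: int = 10,
) -> dict[str, pd.DataFrame]:
    """Per-disease candidate table: drugs sorted by pair score descending.

    Ties preserve drug-name order (stable sort), so all-zero panels keep
    their input ordering. Each row lists the drug's pair score, target
    count, and its top-``top_k_genes`` target genes by node strength in
    the disease network — the signal to inspect when a low-scoring drug
    still hits important biomarkers.
    """
    hyperedges = list(hyperedges)
    out: dict[str, pd.DataFrame] = {}
    for dis in sorted(networks):
        net = networks[dis]
        strengths = net.node_strengths()
        rows = []
        for hyper in sorted(hyperedges, key=lambda h: h.drug_id):
            sc = next(s for s in score_pairs(hyper, networks) if s.disease == dis)
            targets = sorted(
                hyper.refined.get(dis, set()), key=lambda g: (-strengths.get(g, 0.0), g)
            )
            rows.append(
                {
                    "drug": hyper.drug_id,
                    "score": sc.score,
                    "n_targets": sc.n_targets,
                    "top_targets_by_strength": ",".join(targets[:top_k_genes]),
                }
            )
        df = pd.DataFrame(rows)
        if not df.empty:
            df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
        out[dis] = df
    return out
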