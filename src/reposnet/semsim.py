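"""Wang's graph-based GO semantic similarity and gene-level aggregation.

A GO term t is represented by its ancestor closure together with
S-values that decay along the DAG: S_t(t) = 1 and, for any ancestor a,

    S_t(a) = max over children c of a lying in t's ancestor graph of
             w(c -> a) * S_t(c)

with contribution factors w of 0.8 for ``is_a`` and 0.6 for ``part_of``
edges by default. The semantic value SV(t) is the sum of all S-values.
Two terms are compared by

    sim(t1, t2) = sum over shared ancestors a of (S_t1(a) + S_t2(a))
                  / (SV(t1) + SV(t2))

which lies in [0, 1] and equals 1 iff the terms coincide (or share
identical ancestor structure). Gene-level similarity aggregates the
pairwise term similarities of the two genes' annotation sets, by default
with the best-match average (mean of each term's best counterpart in
both directions); ``max`` and ``avg`` over all pairs are also available.

Terms are compared within a single namespace (biological_process by
default); a cross-namespace term pair has no shared ancestry and its
similarity is undefined (returned as NaN, excluded from gene-level
denominators).
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import numpy as np

from .io_formats import GeneAnnotations, GoDag

__all__ = [
    "DEFAULT_RELATION_FACTORS",
    "s_values",
    "semantic_value",
    "term_similarity",
    "gene_similarity",
]

DEFAULT_RELATION_FACTORS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


def s_values(
    term: str,
    dag: GoDag,
    factors: Mapping[str, float] | None = None,
    _cache: dict | None = None,
) -> dict[str, float]:
    """S-values of ``term`` for itself and every ancestor.

    Computed by dynamic programming over the ancestor subgraph in
    topological order (children before parents), so each ancestor's
    S-value is the best decayed path from the term. Pass a dict as
    ``_cache`` to memoize across calls with the same DAG and factors.
    """
    if _cache is not None and term in _cache:
        return _cache[term]
    if term not in dag.graph:
        raise KeyError(f"unknown term {term!r}")
    w = dict(DEFAULT_RELATION_FACTORS if factors is None else factors)
    for rel, f in w.items():
        if not 0.0 < f < 1.0:
            raise ValueError(f"contribution factor for {rel} must lie in (0, 1)")
    nodes = {term} | dag.ancestors(term)
    sub = dag.graph.subgraph(nodes)
    sv: dict[str, float] = {term: 1.0}
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        best = 0.0
        for child in sub.predecessors(node):
            rel = sub.edges[child, node]["relation"]
            cand = w.get(rel, 0.0) * sv.get(child, 0.0)
            if cand > best:
                best = cand
        sv[node] = best
    if _cache is not None:
        _cache[term] = sv
    return sv


def semantic_value(term: str, dag: GoDag, factors: Mapping[str, float] | None = None) -> float:
    """SV(t): sum of the S-values of the term and all its ancestors."""
    return float(sum(s_values(term, dag, factors).values()))


def term_similarity(
    t1: str,
    t2: str,
    dag: GoDag,
    factors: Mapping[str, float] | None = None,
    _cache: dict | None = None,
) -> float:
    """Wang similarity of two GO terms in [0, 1].

    Returns NaN for a cross-namespace pair (no shared ancestry; callers
    exclude such pairs from aggregate denominators).
    """
    for t in (t1, t2):
        if t not in dag.graph:
            raise KeyError(f"unknown term {t!r}")
    ns1, ns2 = dag.namespace.get(t1, ""), dag.namespace.get(t2, "")
    if ns1 != ns2:
        return float("nan")
    sv1 = s_values(t1, dag, factors, _cache)
    sv2 = s_values(t2, dag, factors, _cache)
    shared = set(sv1) & set(sv2)
    denom = sum(sv1.values()) + sum(sv2.values())
    if not shared or denom == 0.0:
        return 0.0
    return float(sum(sv1[a] + sv2[a] for a in shared) / denom)


def gene_similarity(
    g1: str,
    g2: str,
    anns: GeneAnnotations,
    dag: GoDag,
    *,
    namespace: str = "biological_process",
    combine: str = "bma",
    factors: Mapping[str, float] | None = None,
    _cache: dict | None = None,
) -> float:
    """Similarity of two genes from their GO annotation sets.

    Annotations are first restricted to ``namespace``. ``combine`` is one
    of ``bma`` (best-match average, the default), ``max`` or ``avg``.
    Returns NaN when either gene has no annotation in the namespace
    (callers fall back to 0 for edge weighting).
    """
    terms1 = sorted(t for t in anns.terms_of(g1) if dag.namespace.get(t) == namespace and t in dag.graph)
    terms2 = sorted(t for t in anns.terms_of(g2) if dag.namespace.get(t) == namespace and t in dag.graph)
    if not terms1 or not terms2:
        return float("nan")
    sims = np.array(
        [[term_similarity(a, b, dag, factors, _cache) for b in terms2] for a in terms1]
    )
    if combine == "max":
        return float(np.nanmax(sims))
    if combine == "avg":
        return float(np.nanmean(sims))
    if combine == "bma":
        row_best = np.nanmax(sims, axis=1)
        col_best = np.nanmax(sims, axis=0)
        return float((row_best.sum() + col_best.sum()) / (row_best.size + col_best.size))
    raise ValueError(f"unknown combine rule {combine!r}")
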