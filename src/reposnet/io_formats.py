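"""Readers and writers for every external format the pipeline touches.

All other modules consume only the domain types defined here:

* :class:`ExpressionStudy` — a log2 expression matrix with a two-group
  sample design (``reference`` vs ``condition``), covering both the
  normal-plus-disease and the pre/post drug-treatment study layouts.
* :class:`ProbeAnnotation` — probe id → gene symbol mapping.
* :class:`InteractionList` — unordered gene–gene interaction pairs
  (BioGRID tab-delimited flavour).
* :class:`PathwayCatalog` — GMT gene-set membership with an inverse index.
* :class:`GoDag` / :class:`GeneAnnotations` — Gene Ontology DAG (OBO 1.2)
  and gene → GO-term annotations (GAF 2.x or two-column TSV).

Formats are plain text throughout: expression matrices are tab-delimited
with a header row of sample ids; group and annotation files are two-column
TSVs. Gene symbols are compared case-sensitively after trimming
whitespace; no alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "GROUP_REFERENCE",
    "GROUP_CONDITION",
    "ExpressionStudy",
    "ProbeAnnotation",
    "InteractionList",
    "PathwayCatalog",
    "GoDag",
    "GeneAnnotations",
    "read_expression",
    "write_expression",
    "read_probe_annotation",
    "read_interactions",
    "write_interactions",
    "read_gmt",
    "write_gmt",
    "read_obo",
    "read_gaf",
    "write_edge_list",
]

GROUP_REFERENCE = "reference"
GROUP_CONDITION = "condition"
_VALID_GROUPS = (GROUP_REFERENCE, GROUP_CONDITION)

#: Default BioGRID tab-3 column names for the two interactors.
BIOGRID_SYMBOL_A = "Official Symbol Interactor A"
BIOGRID_SYMBOL_B = "Official Symbol Interactor B"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionStudy:
    """A normalized log2 expression matrix with a two-group design.

    Parameters
    ----------
    matrix
        Rows are feature ids (probes or gene symbols), columns are sample
        ids; values are log2-scale intensities.
    groups
        Mapping sample id → group label, one of ``reference`` /
        ``condition``. For a disease study the reference group is the
        normal samples; for a drug-treatment study it is the pre-treatment
        samples.
    study_id
        Identifier of the study (e.g. an accession).
    condition_name
        Name of the disease or drug the condition group represents.
    dose, timepoint
        Optional labels for drug studies with multiple dosages or
        timepoints.
    """

    matrix: pd.DataFrame
    groups: dict[str, str]
    study_id: str = ""
    condition_name: str = ""
    dose: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise FormatError(f"duplicate row ids: {sorted(map(str, dupes))[:5]}")
        samples = list(self.matrix.columns)
        missing = [s for s in samples if s not in self.groups]
        if missing:
            raise FormatError(f"samples without a group label: {missing}")
        extra = [s for s in self.groups if s not in set(samples)]
        if extra:
            raise FormatError(f"group file lists samples absent from the matrix: {extra}")
        bad = {g for g in self.groups.values() if g not in _VALID_GROUPS}
        if bad:
            raise FormatError(f"unknown group labels {sorted(bad)}; expected {_VALID_GROUPS}")
        for label in _VALID_GROUPS:
            if label not in self.groups.values():
                raise FormatError(f"group '{label}' has no samples")
        import numpy as np

        try:
            values = self.matrix.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"expression matrix is not numeric: {exc}") from exc
        if not np.isfinite(values).all():
            raise FormatError("expression matrix contains non-finite values")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.matrix.columns if self.groups[s] == group]

    @property
    def reference_samples(self) -> list[str]:
        return self.samples_in(GROUP_REFERENCE)

    @property
    def condition_samples(self) -> list[str]:
        return self.samples_in(GROUP_CONDITION)


@dataclass
class ProbeAnnotation:
    """Probe id → gene symbol mapping; probes without a symbol map to None."""

    mapping: dict[str, str | None]

    def __post_init__(self) -> None:
        for probe, sym in self.mapping.items():
            if sym is not None and not sym.strip():
                raise FormatError(f"empty gene symbol for probe {probe!r}")


@dataclass
class InteractionList:
    """Unordered, unique gene–gene interaction pairs.

    Pairs are stored canonically as sorted tuples so equality is
    order-independent. Self-interactions are dropped at load (all
    downstream centrality formulas assume simple graphs) and counted in
    ``n_self_loops_dropped``.
    """

    edges: set[tuple[str, str]]
    source: str = ""
    n_self_loops_dropped: int = 0
    n_duplicates_collapsed: int = 0

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise FormatError(f"self-loop {a!r} in InteractionList")
            canon.add((a, b) if a <= b else (b, a))
        self.edges = canon

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self.edges

    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}


@dataclass
class PathwayCatalog:
    """Pathway id → member gene set, with a consistent inverse index."""

    mapping: dict[str, set[str]]
    inverse: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        inv: dict[str, set[str]] = {}
        for pw, genes in self.mapping.items():
            for g in genes:
                inv.setdefault(g, set()).add(pw)
        self.inverse = inv

    def pathways_of(self, gene: str) -> set[str]:
        return self.inverse.get(gene, set())


@dataclass
class GoDag:
    """Gene Ontology DAG restricted to ``is_a`` / ``part_of`` edges.

    ``graph`` is a directed networkx graph with edges pointing child →
    parent, each carrying a ``relation`` attribute. Obsolete terms are
    kept in ``terms`` (so annotations to them can be recognised and
    dropped) but carry no edges.
    """

    graph: nx.DiGraph
    namespace: dict[str, str]
    obsolete: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise FormatError(f"ontology graph contains a cycle: {cycle}")
        for t in self.obsolete:
            if self.graph.degree(t) if t in self.graph else 0:
                raise FormatError(f"obsolete term {t} carries edges")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes) | self.obsolete

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` (excluding itself) along child→parent edges."""
        return nx.descendants(self.graph, term)

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs for ``term``."""
        return [(p, self.graph.edges[term, p]["relation"]) for p in self.graph.successors(term)]


@dataclass
class GeneAnnotations:
    """Gene symbol → set of GO term ids, validated against a :class:`GoDag`."""

    mapping: dict[str, set[str]]
    n_dropped: int = 0

    def terms_of(self, gene: str) -> set[str]:
        return self.mapping.get(gene, set())


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(
    path: str | Path,
    groups_path: str | Path,
    *,
    study_id: str = "",
    condition_name: str = "",
    dose: str | None = None,
    timepoint: str | None = None,
) -> ExpressionStudy:
    """Read a tab-delimited expression matrix plus a two-column group file.

    The matrix file has a header row of sample ids and one feature per
    row; the groups file maps each sample id to ``reference`` or
    ``condition``. A non-numeric cell raises an error naming the row and
    column; a group-file sample absent from the matrix (or vice versa) is
    an error.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in header")
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row ids {dupes[:5]}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise FormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}: {raw.loc[row, col]!r}")
    groups = _read_two_column(groups_path, "sample", "group")
    return ExpressionStudy(
        matrix=numeric,
        groups=groups,
        study_id=study_id or path.stem,
        condition_name=condition_name,
        dose=dose,
        timepoint=timepoint,
    )


def write_expression(study: ExpressionStudy, path: str | Path, groups_path: str | Path) -> None:
    study.matrix.to_csv(path, sep="\t", index_label="feature")
    with open(groups_path, "w") as fh:
        for sample in study.matrix.columns:
            fh.write(f"{sample}\t{study.groups[sample]}\n")


def _read_two_column(path: str | Path, what_key: str, what_val: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns ({what_key}, {what_val})")
            key, val = parts[0].strip(), parts[1].strip()
            if key in out:
                raise FormatError(f"{path}:{lineno}: duplicate {what_key} {key!r}")
            out[key] = val
    return out


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a two-column probe → gene-symbol TSV; empty symbols mean unmapped."""
    mapping: dict[str, str | None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            probe = parts[0].strip()
            if probe in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate probe id {probe!r}")
            sym = parts[1].strip() if len(parts) > 1 else ""
            mapping[probe] = sym or None
    return ProbeAnnotation(mapping)


# ---------------------------------------------------------------------------
# interactions


def read_interactions(
    path: str | Path,
    *,
    symbol_a: str | int = BIOGRID_SYMBOL_A,
    symbol_b: str | int = BIOGRID_SYMBOL_B,
    row_filter: Callable[[pd.Series], bool] | None = None,
    source: str = "",
) -> InteractionList:
    """Read a BioGRID-style tab-delimited interaction file.

    ``symbol_a`` / ``symbol_b`` select the interactor columns by header
    name (default: the tab-3 official-symbol columns) or by integer
    position. ``row_filter`` is an optional per-row hook (e.g. to keep
    only physical interactions); rows for which it returns False are
    skipped. Self-interactions are dropped and duplicate pairs collapsed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols: list[str] = []
    for sel in (symbol_a, symbol_b):
        if isinstance(sel, int):
            if sel >= df.shape[1]:
                raise FormatError(f"{path}: interactor column index {sel} out of range")
            cols.append(df.columns[sel])
        else:
            if sel not in df.columns:
                raise FormatError(f"{path}: missing interactor column {sel!r}")
            cols.append(sel)
    edges: set[tuple[str, str]] = set()
    n_self = 0
    n_dup = 0
    for _, row in df.iterrows():
        if row_filter is not None and not row_filter(row):
            continue
        a, b = row[cols[0]].strip(), row[cols[1]].strip()
        if not a or not b or a == "-" or b == "-":
            continue
        if a == b:
            n_self += 1
            continue
        pair = (a, b) if a <= b else (b, a)
        if pair in edges:
            n_dup += 1
        else:
            edges.add(pair)
    return InteractionList(
        edges=edges,
        source=source or path.name,
        n_self_loops_dropped=n_self,
        n_duplicates_collapsed=n_dup,
    )


def write_interactions(interactions: InteractionList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{BIOGRID_SYMBOL_A}\t{BIOGRID_SYMBOL_B}\n")
        for a, b in sorted(interactions.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> PathwayCatalog:
    """Read a standard GMT file: name, description, then member genes per line."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0].strip()
            members = {g.strip() for g in fields[2:] if g.strip()}
            mapping[name] = mapping.get(name, set()) | members
    return PathwayCatalog(mapping)


def write_gmt(catalog: PathwayCatalog, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for pw in sorted(catalog.mapping):
            genes = "\t".join(sorted(catalog.mapping[pw]))
            fh.write(f"{pw}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# ontology


def read_obo(path: str | Path) -> GoDag:
    """Read an OBO 1.2 ontology, keeping ``is_a`` and ``part_of`` edges.

    Obsolete terms are recorded but stripped of edges. A cyclic ontology
    is rejected.
    """
    multi = obonet.read_obo(str(path), ignore_obsolete=False)
    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    obsolete: set[str] = set()
    for node, data in multi.nodes(data=True):
        namespace[node] = data.get("namespace", "")
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
            continue
        graph.add_node(node)
    for child, parent, rel in multi.edges(keys=True):
        if rel not in ("is_a", "part_of"):
            continue
        if child in obsolete or parent in obsolete:
            continue
        if parent not in graph:
            graph.add_node(parent)
            namespace.setdefault(parent, "")
        graph.add_edge(child, parent, relation=rel)
    return GoDag(graph=graph, namespace=namespace, obsolete=obsolete)


def read_gaf(path: str | Path, dag: GoDag) -> GeneAnnotations:
    """Read gene → GO annotations from GAF 2.x or a two-column TSV.

    Lines starting with ``!`` or ``#`` are comments. GAF rows with a
    ``NOT`` qualifier are excluded; annotations to unknown or obsolete
    terms are dropped with a warning and counted.
    """
    mapping: dict[str, set[str]] = {}
    n_dropped = 0
    valid = set(dag.graph.nodes)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF 2.x
                qualifier, gene, term = fields[3], fields[2].strip(), fields[4].strip()
                if "NOT" in qualifier.split("|"):
                    continue
            elif len(fields) >= 2:  # gene<TAB>term
                gene, term = fields[0].strip(), fields[1].strip()
            else:
                raise FormatError(f"{path}:{lineno}: unrecognised annotation line")
            if term not in valid:
                reason = "obsolete" if term in dag.obsolete else "unknown"
                warnings.warn(f"{path}:{lineno}: dropping annotation of {gene!r} to {reason} term {term}")
                n_dropped += 1
                continue
            mapping.setdefault(gene, set()).add(term)
    return GeneAnnotations(mapping, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# network export helpers


def write_edge_list(graph: nx.Graph, path: str | Path, weight_attr: str = "weight") -> None:
    """Write a 3-column weighted edge list (u, v, weight), sorted for determinism."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            u, v = sorted((str(u), str(v)))
            fh.write(f"{u}\t{v}\t{data.get(weight_attr, 0.0):.10g}\n")
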