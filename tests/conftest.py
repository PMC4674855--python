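from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from reposnet.io_formats import (
    GROUP_CONDITION,
    GROUP_REFERENCE,
    ExpressionStudy,
    GoDag,
)


def make_study(values: dict[str, list[float]], n_ref: int, n_cond: int, study_id: str = "study") -> ExpressionStudy:
    """Build a small ExpressionStudy from per-gene sample values (ref first)."""
    samples = [f"r{i}" for i in range(n_ref)] + [f"c{i}" for i in range(n_cond)]
    matrix = pd.DataFrame(values, index=samples).T
    groups = {s: (GROUP_REFERENCE if s.startswith("r") else GROUP_CONDITION) for s in samples}
    return ExpressionStudy(matrix=matrix, groups=groups, study_id=study_id)


def make_dag(edges: list[tuple[str, str, str]], namespace: str = "biological_process",
             extra_terms: list[str] | None = None) -> GoDag:
    """GoDag from (child, parent, relation) triples."""
    g = nx.DiGraph()
    terms = {t for e in edges for t in e[:2]} | set(extra_terms or [])
    g.add_nodes_from(terms)
    for child, parent, rel in edges:
        g.add_edge(child, parent, relation=rel)
    return GoDag(graph=g, namespace={t: namespace for t in terms})


def random_dag(rng: np.random.Generator, n_terms: int = 15) -> GoDag:
    """Random rooted DAG: term i>0 gets 1–2 parents among lower-index terms."""
    names = [f"T{i:02d}" for i in range(n_terms)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.4 and i > 1)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            g.add_edge(names[i], names[int(p)], relation=rel)
    return GoDag(graph=g, namespace={t: "biological_process" for t in names})


@pytest.fixture
def chain_dag() -> GoDag:
    """root <- a <- b, is_a edges only."""
    return make_dag([("a", "root", "is_a"), ("b", "a", "is_a")])


@pytest.fixture
def toy_obo(tmp_path):
    """A 5-term ontology with one part_of edge, plus an obsolete term."""
    text = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: child A
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: child B
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: grandchild
namespace: biological_process
is_a: GO:0000002 ! child A

[Term]
id: GO:0000005
name: leaf
namespace: biological_process
relationship: part_of GO:0000003 ! child B

[Term]
id: GO:0000099
name: dead
namespace: biological_process
is_obsolete: true
"""
    path = tmp_path / "toy.obo"
    path.write_text(text)
    return path
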