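"""Wang's GO semantic similarity on a tiny hand-built ontology.

S-values decay multiplicatively along the DAG (0.8 per is_a edge,
0.6 per part_of edge); two terms are compared through their shared
ancestors, and genes through the best-match average of their
annotation sets.
"""

import networkx as nx

from reposnet import GeneAnnotations, gene_similarity, s_values, term_similarity
from reposnet.io_formats import GoDag

# chain: root <- a <- b, plus a sibling branch root <- c <- d
g = nx.DiGraph()
for child, parent in [("a", "root"), ("b", "a"), ("c", "root"), ("d", "c")]:
    g.add_edge(child, parent, relation="is_a")
dag = GoDag(graph=g, namespace={t: "biological_process" for t in g.nodes})

print("S-values of term b (decay 0.8 per is_a step):")
for anc, s in sorted(s_values("b", dag).items(), key=lambda kv: -kv[1]):
    print(f"  S_b({anc}) = {s:.3f}")

sim_ab = term_similarity("a", "b", dag)
sim_bd = term_similarity("b", "d", dag)
print(f"\nsim(a, b) = {sim_ab:.4f}   (parent and child: high)")
print(f"sim(b, d) = {sim_bd:.4f}   (only the root is shared: low)")

anns = GeneAnnotations({"gene1": {"b"}, "gene2": {"b", "d"}, "gene3": {"d"}})
print(f"\ngene similarity (best-match average over annotation sets):")
print(f"  gene1 vs gene2 = {gene_similarity('gene1', 'gene2', anns, dag):.4f}")
print(f"  gene1 vs gene3 = {gene_similarity('gene1', 'gene3', anns, dag):.4f}")
print("\nThese per-gene-pair similarities feed the network edge weights.")
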