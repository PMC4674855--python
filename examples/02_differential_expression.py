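"""Moderated differential expression on a simulated disease contrast.

Fits the empirical-Bayes moderated t-test to every gene, adjusts with
Benjamini-Hochberg, and calls genes significant at q < 0.01. With a
planted log2 effect of +/-2 and noise SD 0.3, essentially all 50 planted
genes should be recovered with the correct direction.
"""

from reposnet import SimulationConfig, differential_expression
from reposnet.synthetic import simulate_study_pair

cfg = SimulationConfig(rng_seed=1)
disease_study, _, truth = simulate_study_pair(cfg)

res = differential_expression(disease_study, q_threshold=0.01, method="moderated")
called = res.significant_directions()
planted = truth.disease_genes

hits = {g for g in called if g in planted}
correct_dir = {g for g in hits if called[g] == planted[g]}
print(f"significant at q<0.01: {len(called)} genes")
print(f"planted genes recovered: {len(hits)} / {len(planted)}")
print(f"recovered with the planted direction: {len(correct_dir)} / {len(hits)}")

print("\nstrongest five calls (smallest q):")
top = res.table.nsmallest(5, "q_value")
for row in top.itertuples(index=False):
    tag = "planted" if row.gene in planted else "false positive"
    print(f"  {row.gene}  log2fc={row.log2fc:+.2f}  q={row.q_value:.2e}  {row.direction}  [{tag}]")
print("\nEach line is one gene's fold change, adjusted p-value and regulation call.")
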