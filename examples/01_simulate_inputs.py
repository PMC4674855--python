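"""Generate a complete synthetic input panel with known ground truth.

Writes a disease study, six drug-treatment studies (one true reverser,
five decoys), an interaction network, pathway sets, a small GO DAG and
gene annotations — everything the pipeline needs — into ./sim_inputs/.
"""

from reposnet import SimulationConfig
from reposnet.synthetic import simulate_study_pair, write_simulated_inputs

cfg = SimulationConfig(rng_seed=1)
paths = write_simulated_inputs(cfg, "sim_inputs")

disease, drugs, truth = simulate_study_pair(cfg)
print(f"gene universe: {cfg.n_genes}, planted disease genes: {len(truth.disease_genes)}")
for drug, frac in zip(cfg.drug_names(), cfg.reversal_fractions):
    print(f"  {drug}: reverses {len(truth.reversed_by_drug[drug])} planted genes "
          f"(target fraction {frac})")
print("\nfiles written:")
for name, path in sorted(paths.items()):
    print(f"  {name:18s} {path}")
print("\ndrug01 is the planted therapeutic candidate; the rest are decoys.")
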