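# reposnet

Network-based drug repositioning from public-style gene expression data.

`reposnet` is for computational biologists who want to rank existing
drugs against diseases using the **signature-reversal** hypothesis: a
drug is a repurposing candidate for a disease when the transcriptional
changes it induces run opposite to the disease's own changes, and the
genes it flips sit at important positions in the disease's interaction
network.

## The method

Given a *normal vs disease* expression study and a panel of *pre vs
post drug treatment* studies (log2-scale matrices with two-group
designs), the pipeline:

1. **Significant genes.** Tests every gene with an empirical-Bayes
   moderated t-statistic (gene-wise variances shrunk toward a moment-fit
   prior; Welch's t as an alternative), adjusts p-values with
   Benjamini–Hochberg, and calls genes significant at q < 0.01
   (cancerous diseases) or q < 0.05 (non-cancerous). Up/down regulation
   follows the sign of the log2 fold change. Multiple datasets of one
   disease are combined by union (directions must agree); multiple
   timepoints of one drug dosage by intersection; dosages stay separate.
2. **Reversal targets.** For each (disease, drug), the common
   significant genes with *opposite* direction are the drug's probable
   targets; optionally only disease genes targeted by ≥1 drug are
   carried forward.
3. **Disease networks.** Per disease, a simple graph over its
   significant genes using only interactions internal to that set, with

       node_weight   = norm(degree) + norm(betweenness) + norm(clustering)
       edge_weight   = mean(GO semantic similarity, pathway score)
       pathway score = |common pathways| / |union of pathways|
       node_strength = node_weight + Σ incident edge_weights

   GO similarity is Wang's graph-based measure (S-value decay 0.8 per
   `is_a`, 0.6 per `part_of` edge) aggregated per gene pair by
   best-match average.
4. **Heterogeneous network and hyperedges.** Disease nodes join the
   union gene graph, each linked to its genes with weight
   `1 − rank(G)/N` (genes ranked by the z-score of their node weights);
   drug nodes link to the genes they flip. Each drug's gene
   neighbourhood plus the disease nodes forms a hyperedge whose
   per-disease refined target set keeps only the disease-linked,
   oppositely regulated genes.
5. **Scoring.** With P the target gene's node weight, Q the disease's
   total node weight, S the drug's refined target count for the disease,
   Y the summed weight of the targeted genes and Z = Q:

       score(Ds, G, Dr) = (P/Q) · (1/S)        # disease–gene–drug triple
       score(Ds, Dr)    = Y/Z                  # disease–drug pair, in [0, 1]

   Drugs are ranked per disease by the pair score; each candidate is
   reported with its strongest target genes by node strength, since a
   low-scoring drug hitting key hub genes can still be a candidate.

Because real inputs (GEO studies, BioGRID, GO, KEGG) require downloads,
the package ships a first-class synthetic-data generator that emulates
all five input kinds with planted disease signatures and a planted
reversing drug, so the whole method is testable offline.

## Worked example

```bash
python examples/06_score_and_rank.py
```

simulates a 1000-gene panel (50 planted disease genes, effect ±2.0 log2
units, noise SD 0.3, 5 samples/group; one drug reversing 80% of the
disease genes and five decoys reversing 10%) and runs all stages:

```
disease-drug score matrix (rows = drugs):
        simulated_disease
drug
drug01             0.9586
drug02             0.0530
drug03             0.0911
drug04             0.0930
drug05             0.0904
drug06             0.0977

planted reversing drug: drug01; ranked first: True
```

`drug01` reverses genes carrying 95.9% of the disease network's node
weight — the planted therapeutic signal — while the decoys stay below
0.1. The other `examples/*.py` scripts walk through each stage
(simulation, differential expression, reversal targets, network
construction, GO similarity) with printed, annotated output.

The same stages are available from the shell:

```bash
reposnet simulate --seed 1 --out sim/
reposnet deg --study sim/disease_matrix.tsv --groups sim/disease_groups.tsv --q 0.01 --out deg.tsv
reposnet pipeline --config run.yaml      # all six stages + report bundle
```

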