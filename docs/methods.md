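# Methods

This note records the statistical model, the conventions chosen where
the method leaves room, the synthetic-data generator's assumptions, and
the numerical details a maintainer would need. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Differential expression

Each contrast is a two-group comparison of log2-scale expression
(reference vs condition; normal vs disease, or pre vs post treatment).
Per gene, `log2fc = mean(condition) − mean(reference)`.

**Moderated t (default).** The pooled gene-wise variance s²_g with
d = n₁ + n₂ − 2 degrees of freedom is shrunk toward a prior s₀²
estimated across genes:

    s²_post = (d₀·s₀² + d·s²_g) / (d₀ + d)

(d₀, s₀²) come from matching the mean and variance of log s²_g to the
theoretical moments of log of a scaled F variate (digamma/trigamma
moment equations; the trigamma inverse is solved by Newton iteration).
When the empirical spread of log-variances does not exceed the
chi-square sampling noise, d₀ = ∞ and every gene gets the common
variance. The moderated statistic t = log2fc / √(s²_post(1/n₁+1/n₂)) is
referred to a t distribution on d + d₀ df (normal when d₀ = ∞). One
test compares the whole procedure against the R/Bioconductor
implementation of the same empirical-Bayes linear-model approach on a
random fixture (rtol 1e-4). Welch's t-test is available as
`method="welch"`.

- Zero-variance genes: s²_post is floored at machine-epsilon scale
  (eps², ≈4.9e-32) so a nonzero mean difference cannot yield p = 0.
- q-values: Benjamini–Hochberg step-up over all genes of the study
  (statsmodels); validated against an independent hand-rolled step-up
  in the tests.
- Thresholds: q < 0.01 for the `cancerous` disease class, q < 0.05 for
  `non_cancerous`; both overridable per run.
- Direction: sign of log2fc; exactly 0 means no direction and exclusion
  from the up/down sets (the positive/negative rule is silent on 0).

**Combination rules.** Datasets of one disease: union of significant
genes, a gene kept only when every dataset calling it agrees on
direction (disagreements are flagged `conflicting` and excluded, with
provenance retained). Timepoints of one drug dosage: intersection over
all timepoints with direction agreement. Dosages are never merged —
each dosage is its own drug signature. The platform homogeneity of
combined datasets is recorded but not enforced.

## Reversal targets

Per (disease, drug): intersect the two signatures and keep
direction-discordant genes. The Step-2 restriction (disease genes kept
only if ≥1 drug targets them) is a pipeline flag, on by default;
turning it off realises the "use all significant disease genes"
variant. The scoring denominators Q and Z are the total node weight of
the disease network *as built*, so they follow this flag consistently.

## Disease networks

Only interactions with both endpoints significant survive; untouched
genes stay as isolated nodes (they carry weight through the
normalization and the denominators). Centralities are computed on the
unweighted simple graph: degree; shortest-path betweenness (undirected,
endpoints excluded, unnormalized — a subsequent min–max scaling makes
any constant factor irrelevant); local clustering coefficient. Each
metric is min–max normalized over the network's nodes; a metric
constant across nodes (e.g. clustering in a triangle-free graph)
contributes 0 for every node rather than an arbitrary constant. Node
weight = sum of the three normalized metrics ∈ [0, 3].

Edge weights combine two features: Wang-similarity of the gene pair
(best-match average over their GO term sets, biological_process
namespace by default) and the pathway score
|P(u)∩P(v)| / |P(u)∪P(v)|. The written-out combination
"average of GO similarity and pathway score" is read as the arithmetic
mean; `combiner="sum"` and `denominator="total"` (|P(u)|+|P(v)|) are
available because both readings are defensible. Missing annotations or
pathway data score that component 0 instead of dropping the edge. Node
strength = node weight + Σ incident edge weights.

## Wang similarity

S_t(t) = 1; S_t(a) = max over children c of a (within t's ancestor
graph) of w(c→a)·S_t(c), with w = 0.8 (`is_a`) / 0.6 (`part_of`);
computed by dynamic programming in topological order and memoized per
term (memoization is required for cost on real ontologies and
unobservable in results). sim(t₁,t₂) sums shared-ancestor S-values over
SV(t₁)+SV(t₂). Cross-namespace pairs are undefined (NaN) and never
enter best-match-average denominators; gene-level aggregation defaults
to BMA with `max` and `avg` as options. Which GO namespace real
analyses should use is genuinely open; biological_process is the
default and configurable.

## Heterogeneous network, hyperedges, scores

Disease–gene edge weight: node weights z-scored within the disease
(population SD; all z = 0 when SD = 0), genes ranked by z descending
(rank 1 = top; ties broken lexicographically so runs are
deterministic), weight = 1 − rank/N ∈ [0, 1). The weights of ranks 1..N
always sum to (N−1)/2 — asserted in the tests. A gene significant for
several diseases keeps one node but one weight *per disease context*,
stored on the disease–gene edge. Disease nodes' own centrality weights
can be computed on the drug-free heterogeneous graph; they are exposed
but consumed by nothing.

One hyperedge per drug: its adjacent gene nodes plus all disease nodes;
the per-disease refined target set keeps genes linked to that disease
node and oppositely regulated by the drug for it. Scores: triple
= (P/Q)(1/S), pair = Y/Z (definitions in the README). S counts only
refined targets — genes the drug perturbs that are not disease genes
never enter S. The identity Σ_G triple = pair/S is exact algebra and
asserted to 1e-12. Drugs with no targets keep an empty hyperedge and
score 0. Rankings are per disease by pair score, stable under ties,
and annotate each drug with its top target genes by node strength (the
"important biomarkers" signal for low-scoring candidates) rather than
emitting an automatic verdict.

## Synthetic data

The generator emulates RMA-normalized two-group microarray studies:
per-gene baselines ~ N(7, 1) on the log2 scale, i.i.d. Gaussian noise
(SD 0.3), planted disease genes shifted ±2.0 log2 units in the
condition group. Defaults: 1000 genes, 50 planted, 5 samples/group, six
drugs — the first reverses 80% of the planted genes (shift opposite to
the disease direction), five decoys reverse 10%; every drug also
perturbs 20 random non-disease genes (a modest off-target burden so
drug signatures are not pure reversals).

Support data: the interactome is a growing preferential-attachment
graph (3-node seed triangle, 2 degree-proportional attachments per new
node; an Erdős–Rényi alternative is available), plus extra edges among
the planted disease genes with probability 0.1 per pair. The latter
encodes disease-module enrichment — disease genes interact with each
other far above background in real interactomes, and without it the
induced network on ~50 significant genes of a 1000-gene background
graph has almost no edges, the degenerate regime in which this method's
own workflow discards a disease for having too few interactions. The
module density (average degree ≈ 5) is in the range real disease
networks of this kind show. Pathways are blocks grown from a seed
gene's network neighbourhood (so co-pathway genes tend to interact);
the GO DAG is a small layered tree-with-shortcuts with genes annotated
to leaf terms, pathway comembers sharing "home" leaves.

All randomness flows from a single `numpy` Generator per call, seeded
from `rng_seed`: identical configs give byte-identical outputs.

**What passing tests do and do not show.** The generator has no batch
effects, probe-level artifacts, correlated noise, or realistic pathway
topology, and its effect sizes are homogeneous. Recovery of the planted
drug under these conditions demonstrates that the pipeline's stages
compose correctly and that the scoring separates strong reversal from
weak, not that the method is calibrated for any particular real
disease.

## Problem sizes and numerics

The simulation experiments run the full pipeline at the default
conditions (1000 genes, 100 seeds for recovery; 200 replicates for the
null-FDR check); the brute-force centrality oracle covers all labeled
graphs on ≤5 nodes, the complete ≤7-node graph atlas, and 50 random
graphs each at 8 and 30 nodes (an exhaustive non-isomorphic enumeration
at 8 nodes would need an external geng-style enumerator and adds
nothing to coverage of the formulas). Determinism is checked bytewise
over a complete file-driven run. Oracle tolerances: 1e-9 for
betweenness, 1e-12 for clustering, Wang S-values and BH q-values, 1e-12
for the score-conservation identity.

## Known limitations

- No multi-factor designs, paired samples, or batch covariates in the
  DE stage.
- Gene symbols are matched case-sensitively with no alias resolution;
  identifier hygiene is the caller's job.
- Reversal is direction-only; fold-change magnitude never enters the
  scores (the scoring model assumes the drug affects each target
  equally).
- Information-content similarities (Resnik/Lin) are out of scope; only
  Wang's measure is provided.
- Diseases whose networks fall below the interaction floor are flagged,
  not dropped — that judgement stays with the analyst.
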