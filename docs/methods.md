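# Methods

`vinemet` re-implements, as a tested pipeline, a two-cultivar analysis of
grapevine (*Vitis vinifera*) leaf metabolite profiles under two growth
temperatures (25 and 35 °C): per-metabolite differential abundance, covariance
PCA of log10 profiles, and Spearman correlation networks built per cultivar
and compared edge-by-edge, with graph-property reports. Because no raw
per-replicate data accompany the study the pipeline emulates, a synthetic
cohort generator with planted ground truth drives all testing.

## Synthetic cohort model

Abundances are lognormal. On the log10 scale, the mean for sample *s* and
metabolite *m* is

```
log10 baseline_m + log10 tempFC_m[cultivar] · 1[35 °C] + log10 cultFC25_m · 1[Cs]
```

with multivariate-normal noise of marginal standard deviation `noise_sd` and a
block-diagonal correlation: metabolites of the same biochemical class share a
planted correlation `rho_block`, cross-class pairs are independent.
Equicorrelated blocks with `rho_block ∈ [0, 1)` are positive semidefinite for
every block size; anything outside that range is rejected naming the class.

Parameters and defaults:

| parameter | default | units / rationale |
|---|---|---|
| `n_replicates` | 12 | per cultivar × temperature cell, the printed n |
| `noise_sd` | 0.10 | log10 units (~26% CV), a realistic GC–MS replicate spread; the study reports no variance, so this is a package choice made once |
| `block_correlation` | 0.3 per class | modest within-pathway co-response; tests that probe edge recovery plant 0.85 explicitly |
| `baseline_mean` | 100 | arbitrary relative units (internal-standard normalized) |
| `seed` | 1, explicit | every run is reproducible; same config ⇒ bit-identical table |

The planted effects are the two published fold-change tables, cell for cell:
the 35/25 °C ratio per cultivar for 38 metabolites, and the Cs/Sh ratio per
temperature for 22. The default panel is their union (44 metabolites after
name harmonization) plus four metabolites named only in the network
discussion (Thr, GABA, Pyroglutamate, Tartarate) with neutral effects, giving
48 — the node count of the published networks. Each metabolite carries one of
six biochemical classes (amino acid, glycolysis, TCA cycle, non-glycolytic
sugar, flavonoid, carboxylic acid) assigned by the package from standard
pathway membership.

Two parametrization notes. First, the four printed values per metabolite
(two temperature ratios, two cultivar ratios) overdetermine the four cell
means; the generator plants baseline, the two temperature fold changes and
the 25 °C cultivar ratio, so the 35 °C cultivar ratio is implied. Second,
each of the 12 samples per cell carries a unique vine id with sampling day
assigned cyclically, so the day-averaging step of the differential module is
an identity on synthetic cohorts and n = 12 is the effective test size.

What a green test establishes — and what it does not. The generator emulates
the factorial design, multiplicative effects and class-level co-response; it
does not emulate day-to-day drift, vine-level random effects, heteroscedastic
measurement error, detector saturation (the study itself flags sucrose and
inositol as out of linear range), or missing values. Recovery results
therefore validate the pipeline's statistics, not the instrument model.

## Differential abundance

Fold change is the ratio of arithmetic group means of raw (not log)
abundances; under the lognormal noise model the shared noise factor cancels,
so the estimator converges to the planted fold change. Significance is a
two-sided equal-variance Student's t by default (Welch via `equal_var=False`),
or Tukey's HSD over the four cultivar × temperature cells. Shapiro–Wilk (per
group) and Bartlett (across groups) are computed as gate checks; failures log
and proceed. No multiple-testing correction is applied by default — the
emulated analysis reports per-metabolite p < 0.05 — with Benjamini–Hochberg
behind the `fdr` flag.

The "average change" summary is formalized as mean |FC − 1| × 100 over
significant metabolites (the source states no formula); mean |log2 FC| is
reported alongside as the symmetric alternative.

A practical caveat found while testing: on raw-scale lognormal data the cell
variances scale with cell means, so Tukey's pooled variance makes it
underpowered for low-mean cells relative to the pairwise t — the two routes
are both available and both reported, but they are not nested in general.

## PCA

Covariance PCA (mean-centered, unscaled) of log10 profiles via
eigendecomposition; unit-variance scaling behind a flag. Signs are fixed by
making the largest-|loading| entry of each component positive, so outputs are
backend-stable. Explained-variance fractions are non-increasing and sum to
≤ 1; scores reconstruct as centered data × loadings to machine precision
(both are tested, plus an sklearn cross-check).

## Correlation networks

Per variety: every 35 °C sample is divided by the variety's own mean 25 °C
control abundance per metabolite (all controls by default; `n_control`
restricts to the first *k* to reproduce a fixed-chamber convention). Spearman
ρ is the Pearson correlation of average ranks. Two-sided significance:

* **exact permutation** for n ≤ 9 — full enumeration of the n! rank
  permutations, tie-aware, vectorized;
* **t approximation** otherwise — t = ρ√((n−2)/(1−ρ²)) with n−2 df; |ρ| = 1
  falls back to the exact tail 2/n!.

The t approximation (identical to scipy's) is ~20% anticonservative around
ρ ≈ 0.7 at n = 12 relative to the exact permutation null; at the pipeline's
working α = 0.05 the accept/reject decisions coincide (tested), but exact p
values in that tail should not be over-read.

Filtering: keep |ρ| ≥ 0.5 and p < 0.05 (both configurable); under the default
`positive_only` policy negative survivors are dropped, since an edge is
defined as a significant positive co-response. Constant profiles are excluded
with a logged notice, and the per-stage attrition (pairs scanned, passing
|ρ|, passing p, negatives dropped) is logged for auditability. Raising the
threshold or lowering α can only remove edges (property-tested). Nodes are
the metabolites incident to a retained edge.

Comparison: an edge is *common* when the same unordered pair occurs in both
varieties' networks; the rest are variety-unique. Percent common is
100 × |common| / |edges of that variety|. Graph properties are reported for
both the full filtered networks and the unique-edge networks, since the
emulated study does not state which variant its property table used.

## Graph metrics

All metrics treat the network as simple, undirected, unweighted (ρ is an
attribute, never a weight). Diameter is the maximum finite geodesic, so
disconnected networks still get a value; an edgeless graph reports null.
Transitivity is 3 × triangles / connected triples. Modularity is
Newman–Girvan Q = Σ_c (e_cc − a_c²), exactly 0 for the single community, and
is evaluated under three schemes:

* **biochemical** — the fixed class partition;
* **edge betweenness** (Girvan–Newman) — divisive removal of the
  max-betweenness edge, recomputed each step, ties broken by lexicographic
  sorted node pair; Q is tracked against the original graph along the
  component-partition trajectory and the max-Q partition returned (Q ties
  favor the coarser partition). Known limitation, kept as a regression test:
  the divisive hierarchy cannot reach the global max-Q partition on some
  graphs — on one 6-node example every max-betweenness trajectory detaches a
  peripheral node first and caps the reachable Q at 0.01 vs the true 0.20 —
  so agreement with exhaustive search holds for modular structures (bridged
  cliques, K₄) but is not a theorem;
* **walk-trap** (t = 4 steps, the de-facto default) — agglomerative merging
  of adjacent communities minimizing the Ward-style variation
  Δσ = (1/n)·|C₁||C₂|/(|C₁|+|C₂|)·r²(C₁,C₂), where r is the degree-weighted
  Euclidean distance between mean t-step transition-probability profiles;
  components are clustered independently (Q is additive over them) and the
  max-Q merge level is returned. Cross-checked against igraph's walktrap on
  planted two-block graphs.

## Numerical and degenerate-input choices

* Temperatures are categorical strings ("25", "35") — never arithmetic.
* Edges are stored with the lexicographically smaller endpoint first; all
  writers sort, so equal inputs give byte-identical files.
* Zero or negative abundances are rejected at table construction with row and
  column coordinates (log10 must be defined).
* All-constant groups: t-test returns NaN with a warning; Shapiro–Wilk skips
  groups with n < 3 or zero range, with a notice.
* Exact-permutation comparisons use a 1e-12 slack on |ρ| so ties in the null
  distribution count as at-least-as-extreme.
* The pipeline config hash covers the analysis-defining fields (not the
  output directory) and stamps every JSON artifact together with the seed.

## Known limitations

* The published dataset-dependent numbers (node/edge counts, diameters,
  modularities, PCA variance fractions, significance counts) depend on
  undeposited raw data and are not reproduction targets; synthetic-recovery
  and arithmetic-consistency checks stand in for them.
* Tukey vs t (above); t-approximation tail behavior (above); divisive max-Q
  reachability (above).
* The generator's blocks are equicorrelated within class — real pathway
  co-response is graded and cross-class correlations exist (the published
  networks show cross-class edges); recovery rates under the planted model
  are therefore upper bounds on what graded structure would give.
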