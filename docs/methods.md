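# Methods

## Stability score

The Gini coefficient of a gene's expression vector is computed from the
sorted values as `G = 2 Σ_i i·x_(i) / (n Σ x) − (n+1)/n`, which is
algebraically identical both to the pairwise mean-absolute-difference form
`Σ_ij |x_i − x_j| / (2 n² μ)` and to `1 − 2·area` under the trapezoidally
interpolated Lorenz curve anchored at (0, 0). This is the *population*
(uncorrected) estimator — no `n/(n−1)` bias factor — because the
trapezoidal Lorenz-area definition corresponds to it; results are therefore
directly comparable across tools that use the area definition. The tests
verify the three forms agree to 1e−10 on a thousand random vectors.

Conventions for degenerate input:

* an all-zero gene (`μ = 0`) has an *undefined* Gini, carried as NaN with a
  `zero_total` flag; such genes are retained in profiles but excluded from
  ranking, selection and all statistics;
* zero-expression samples are *included* for genes that have any signal —
  zeros are genuine inequality, and dropping them would erase exactly the
  tissue-restricted pattern the score is meant to capture;
* the score is scale- and permutation-invariant, bounded by `1 − 1/n`, and
  respects the Pigou–Dalton transfer principle (property-tested).

## Selection rules

Two selection modes, both operating only on defined-Gini genes:

* **bottom-N** — exactly N genes with the lowest Gini; ties at the cutoff
  broken by ascending gene ID for determinism. Used when matching a
  benchmark list's size.
* **bottom-percentile** — all genes at or below the P-th percentile
  (linear interpolation between closest ranks; the same convention is used
  everywhere percentiles appear, including the benchmark 90th-percentile
  ratio and percentile-rank conversion, which uses average ranks for ties).
  Default P = 20.

## TPM conversion and identifier handling

Read-per-exon-base matrices convert to TPM per sample as
`TPM_is = (r_is / L_ie) / Σ_i (r_is / L_ie) × 1e6`; converter output columns
sum to 1e6 (checked to 1e−6 relative), all-zero columns stay zero and are
flagged. Imported TPM matrices are trusted but marked unverified. Duplicate
gene rows are an error, never merged — any aggregation rule would silently
change Gini values. Identifier maps are consumed as files; genes without a
target are discarded *and reported*, and many-to-one mappings raise an
error listing the collisions (there is no defensible expression merge rule).

## Enrichment

Over-representation p-value `P(X ≥ k)` and under-representation `P(X ≤ k)`
with `X ~ Hypergeometric(N, K, n)`, BH step-up FDR across tested terms,
enrichment called at q < 0.05, BP aspect only, direct gene-to-term
annotations without ontology-graph propagation. Term coverage is
operationalized as `k/K` within the dataset universe.

The compounded background runs a first-pass over-representation analysis of
each dataset's selection against its full universe and keeps the union of
terms enriched in at least one dataset; if nothing is enriched anywhere it
falls back to all annotated terms with a warning. Second-pass analyses
restrict to the background terms and, by default in the pipeline, also
restrict each universe to genes annotated by at least one background term
(`restrict_universe` switch). **Known limitation:** with few, small terms —
as in the synthetic defaults of 200 terms with ~20 planted — the universe
restriction concentrates the universe on the very genes that drove the
background, flattening the second-pass signal. This is a scale effect: with
annotation sets whose background covers most genes the restriction is mild.
Recovery benchmarks therefore measure enrichment against the full dataset
universe.

Common/exclusive term-set comparison: *common* terms are enriched in every
dataset; a group's *exclusive* terms are enriched in at least one of its
datasets and in none of any other group's.

## Essentiality statistics

Six-replicate RNAi arrest counts classify as G1 (≥5 arrested), G2 (3–4),
G3 (≤2); G4 marks genes without a scorable population and G5 untested
genes. Group-vs-rest comparisons report three tests:

* left-tailed Wilcoxon rank-sum (exact enumeration when both groups have
  ≤20 untied observations, normal approximation with tie correction
  otherwise; two fully tied groups give p = 1 by convention);
* two-sample KS (scipy, exact for small samples);
* an exact one-sided binomial sign test of falling below the overall
  median: ties to the median dropped, `p = P(Binomial(m, ½) ≥ k)`. Genes
  with Gini exactly 0 are excluded from the sign test (and from the median)
  because a zero Gini in sparse aggregated single-cell data typically
  reflects detection in one aggregate rather than genuine stability; an
  `exclude_zero_gc` flag (default off) extends the exclusion to the
  rank-sum/KS tests.

All three implementations are checked against exhaustive permutation or
binomial enumeration for group sizes up to 8.

## Cross-species analysis

Per-organism Gini profiles align on 1:1 ortholog rows; a row is kept only
when every organism has a defined Gini for it. The comparison set is the
union of each organism's bottom-20th-percentile genes. Organisms are
compared by Spearman correlation, clustered by average linkage on `1 − ρ`
(linkage choice is a documented package decision; merge ties resolve by
label order, yielding a deterministic caterpillar when all distances tie),
and the tree is emitted as Newick with ultrametric branch lengths. PCA
treats organisms as variables and genes as observations, mean-centers
columns without scaling (Gini already lives on [0, 1]), and fixes each
component's sign so its largest-|loading| entry is positive; scores times
transposed loadings reconstruct the centered matrix to 1e−9. The top-k /
middle-k / bottom-k PC1 score lists (middle = the k rows straddling the
median rank; ties by row ID) name the clade-specific and shared stable
genes.

## Synthetic data

The generator emulates the structure the analysis assumes, at desk scale:

* **Expression** (defaults: 5000 genes × 30 samples, 20% stable): stable
  genes draw a log-normal baseline around 20 abundance units (σ = 0.6 —
  modest levels, matching the observation that housekeeping genes are not
  highly expressed) times multiplicative log-normal noise with CV 0.1;
  variable genes are expressed log-normally around 200 in a random ~20% of
  samples (at least one) and are exactly zero elsewhere. Stable genes land
  at Gini ≈ 0.05, variable genes ≈ 0.85.
* **Annotations** (defaults: 200 BP terms, sizes 10–50, 10% planted):
  planted terms draw ≥80% of members from stable genes, null terms draw
  uniformly.
* **Essentiality** (defaults: P(essential) = 0.5 for stable vs 0.05 for
  variable genes; arrest probability per replicate 0.9 vs 0.05 out of 6):
  labels then classify through the RNAi rule.
* **Multi-organism** (defaults: 9 organisms in clades of 5 and 4, 3000
  ortholog rows, 15 samples each, 20% shared-stable, 10% clade-stable per
  clade): a stable gene keeps one per-gene noise CV (uniform 0.05–0.3)
  across all organisms where it is stable, which is what makes Gini vectors
  correlate within clades; variable genes have independent sample structure
  everywhere.

Every generator is bit-deterministic given its seed; the pipeline and CLI
derive per-stage substream seeds from a master seed via `SeedSequence`.

What the generator does *not* model: count noise and library-size effects,
scRNA-seq dropout, correlated tissue blocks across genes, ontology DAG
structure, batch effects. Passing recovery tests therefore demonstrate that
the machinery is correct and well-calibrated on data with the assumed
structure, not that the score is robust to every artifact of real
compendia.

## Problem sizes and numerical choices

Recovery benchmarks use 20 seeds at the generator defaults above; the
label-permuted null calibration uses 200 permutations of one simulated
dataset (the permuted G1 group is a few hundred genes, so the discrete
sign-test p-value support is fine enough for a KS-vs-uniform comparison).
Oracle agreements use 1000 random vectors (Gini, BH), all hypergeometric
configurations with N ≤ 12, and permutation enumeration at group sizes ≤ 8.
Tolerances: 1e−10 for analytic-oracle agreement, 1e−9 for PCA
reconstruction and variance conservation, 1e−6 relative for TPM column
sums. Pipeline outputs print floats at 10 significant digits and JSON with
sorted keys, making reruns byte-identical under a fixed config and seed.
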