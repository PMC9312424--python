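# ginigenes

Quantitative identification and testing of **housekeeping genes** from gene
expression matrices, built around the Gini coefficient as an
expression-stability score.

Housekeeping genes are classically described by four properties: stable
expression across cell types and conditions, participation in basic cellular
maintenance, essentiality, and conservation across species. `ginigenes`
operationalizes the first property and tests the other three against it:

* **Stability score.** For a gene with expression `x_1 … x_n` over `n`
  samples, the Gini coefficient is the ratio of the area between the Lorenz
  curve and the line of equality to the total area under the line of
  equality; on discrete data this equals

  `G = Σ_i Σ_j |x_i − x_j| / (2 n² μ)`

  with `μ` the mean. `G = 0` for perfectly even expression, `(n−1)/n` when a
  single sample carries everything, and it is undefined when `μ = 0`.
  Genes in the low tail ("Gini genes") — the bottom-N by Gini, or the genes
  at or below the bottom 20th percentile — are the stability-defined
  housekeeping candidates.
* **Function.** Hypergeometric GO over/under-representation of Gini genes
  (BP aspect, BH FDR at 0.05), with a *compounded background*: the union of
  terms enriched in at least one dataset's first-pass analysis becomes the
  shared term universe, making term coverage (`k/K`) comparable across
  datasets of very different sizes.
* **Essentiality.** Gini distributions of essentiality classes (e.g. the
  high-confidence class of a six-replicate RNAi arrest screen, arrested in
  ≥5/6 treatments) are compared to the remaining genes with a left-tailed
  Wilcoxon rank-sum test, a two-sample KS test, and an exact binomial sign
  test against the overall median (zero-Gini genes excluded from the sign
  test).
* **Conservation.** Per-organism Gini vectors aligned on 1:1 orthologs,
  Spearman-correlated, clustered by average linkage on `1 − ρ`, and embedded
  by PCA; extreme PC1 scores pick out clade-specific stable genes.

A fully deterministic synthetic-data generator produces expression matrices
with planted stable genes, GO-like annotations with planted terms,
essentiality labels biased toward stable genes, and multi-organism ortholog
sets with clade structure, so every stage is testable without external
downloads.

## Worked example

Simulate a 2000-gene, 24-sample dataset (20% planted stable genes), score
it, and select the bottom 20th percentile:

```sh
ginigenes simulate --n-genes 2000 --n-samples 24 --seed 42 --outdir demo
ginigenes gini demo/expression.tsv --out demo/profile.tsv
# -> wrote 2000 gene profiles to demo/profile.tsv
ginigenes select demo/profile.tsv --method bottom_percentile --threshold 20 \
    --out demo/gini_genes.txt
# -> selected 400 genes (cutoff Gini 0.490199)
```

The profile TSV holds one row per gene:

```
             gc  n_samples  mean_expr  median_expr  zero_total
g00000   0.9217         24    16.8111       0.0000       False
g00001   0.0543         24     6.2927       6.1618       False
g00002   0.0649         24    13.2476      13.1382       False
```

`g00000` is expressed in only a few samples (median 0, Gini 0.92 — a
tissue-restricted gene); `g00001` and `g00002` are stable (Gini ≈ 0.05–0.06).
Against the generator's truth file, the 400 selected genes recover **100%**
of the planted stable genes; the median Gini is **0.053** for stable genes
and **0.845** for variable ones.

The same stages run end-to-end from a YAML config (`ginigenes run --config
cfg.yaml --outdir report`), producing per-dataset profiles and selections,
cross-dataset correlation tables, enrichment tables, essentiality
comparisons, cross-species outputs (correlation matrix, Newick tree, PCA
scores/loadings), and a machine-readable `summary.json`. Every library
function (`gini_profile`, `select_gini_genes`, `hypergeometric_enrichment`,
`compare_gc_by_group`, `analyze_cross_species`, …) is importable directly
from `ginigenes`.

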