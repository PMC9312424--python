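"""Statistics relating expression stability to magnitude and across datasets.

Covers: Spearman correlation between a gene's Gini coefficient and its median
expression, cross-dataset Gini correlations on shared genes, the
benchmark-vs-all 90th-percentile Gini ratio, the one-sided rank-sum check
that a selection made in one dataset is also low-Gini in another, and the
subsampling curve of mean Gini against sample count.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gini import matrix_gini
from .io import ExpressionMatrix, GeneList

__all__ = [
    "gc_expression_correlation",
    "cross_dataset_gc_correlation",
    "benchmark_percentile_ratio",
    "cross_selection_gc_test",
    "subsample_mean_gc",
    "wilcoxon_rank_sum_less",
]


def _spearman(a: np.ndarray, b: np.ndarray) -> tuple:
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=3)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(a, b)
    return float(rho), float(p)


def gc_expression_correlation(profiles: pd.DataFrame) -> tuple:
    """Spearman correlation between Gini coefficient and median expression.

    Undefined-Gini genes are excluded. Returns ``(rho, p)``; both NaN (with a
    warning) when either vector is constant.
    """
    defined = profiles[profiles["gc"].notna()]
    if len(defined) < 3:
        raise ValueError("need at least 3 genes with defined Gini")
    return _spearman(defined["gc"].to_numpy(), defined["median_expr"].to_numpy())


def cross_dataset_gc_correlation(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame) -> tuple:
    """Spearman correlation of Gini coefficients on the shared-gene set.

    Returns ``(rho, p, n_shared)`` where ``n_shared`` counts genes with a
    defined Gini in both datasets.
    """
    shared = profiles_a.index.intersection(profiles_b.index)
    a = profiles_a.loc[shared, "gc"]
    b = profiles_b.loc[shared, "gc"]
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared genes with defined Gini")
    rho, p = _spearman(a[ok].to_numpy(), b[ok].to_numpy())
    return rho, p, int(ok.sum())


def benchmark_percentile_ratio(profiles: pd.DataFrame, benchmark: GeneList, q: float = 90.0) -> float:
    """Ratio of the benchmark genes' q-th percentile Gini to the all-gene one.

    Percentiles use linear interpolation. A ratio well below 1 means the
    benchmark set sits in the stable (low-Gini) tail of the dataset.
    """
    defined = profiles[profiles["gc"].notna()]
    bench = defined.loc[defined.index.isin(benchmark.genes), "gc"]
    if bench.empty:
        raise ValueError("no benchmark genes with defined Gini in this dataset")
    return float(np.percentile(bench.to_numpy(), q) / np.percentile(defined["gc"].to_numpy(), q))


def wilcoxon_rank_sum_less(group: np.ndarray, complement: np.ndarray) -> float:
    """Left-tailed Wilcoxon rank-sum p-value that ``group`` values are lower.

    Exact null enumeration when both groups have <= 20 observations and there
    are no ties; normal approximation with tie correction otherwise. When
    every observation in both groups is identical the distribution is
    degenerate and p = 1 by convention (no evidence of a shift).
    """
    group = np.asarray(group, dtype=float)
    complement = np.asarray(complement, dtype=float)
    if group.size < 2 or complement.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([group, complement])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(group.size, complement.size) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(group, complement, alternative="less", method=method)
    return float(res.pvalue)


def cross_selection_gc_test(selection: GeneList, profiles_b: pd.DataFrame) -> float:
    """Do genes selected in dataset A have lower Gini in dataset B?

    Left-tailed Wilcoxon rank-sum of the selection genes' Gini in B against
    all other defined-Gini genes in B.
    """
    defined = profiles_b[profiles_b["gc"].notna()]
    in_sel = defined.index.isin(selection.genes)
    group = defined.loc[in_sel, "gc"].to_numpy()
    rest = defined.loc[~in_sel, "gc"].to_numpy()
    if group.size < 2 or rest.size < 2:
        raise ValueError("selection or its complement has fewer than 2 genes in the target dataset")
    return wilcoxon_rank_sum_less(group, rest)


def subsample_mean_gc(
    m: ExpressionMatrix,
    sizes,
    reps: int = 100,
    seed=None,
) -> pd.Series:
    """Mean Gini coefficient as a function of subsampled sample count.

    For each size, ``reps`` subsets of samples are drawn without replacement;
    within each rep the mean is taken over genes with a defined Gini, and the
    rep means are averaged. Deterministic given ``seed``. Sizes must satisfy
    ``2 <= size < n_samples`` (at the full sample count there is nothing to
    subsample).
    """
    sizes = [int(s) for s in sizes]
    for s in sizes:
        if not 2 <= s < m.n_samples:
            raise ValueError(f"subsample size {s} outside [2, {m.n_samples - 1}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for s in sizes:
        rep_means = np.empty(reps)
        for r in range(reps):
            cols = rng.choice(m.n_samples, size=s, replace=False)
            gc = matrix_gini(m.values[:, cols])
            rep_means[r] = np.nanmean(gc)
        out[s] = rep_means.mean()
    return pd.Series(out, name="mean_gc").rename_axis("n_samples")
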