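"""Per-gene Gini coefficients, Lorenz curves, and Gini-gene selection.

The Gini coefficient G of a gene's expression vector x over n samples is the
ratio of the area between the Lorenz curve and the line of equality to the
total area under the line of equality. On discrete data with trapezoidal
Lorenz interpolation this equals the mean-absolute-difference form

    G = sum_i sum_j |x_i - x_j| / (2 n^2 mu)

with mu the mean of x. G is 0 for perfectly even expression, (n-1)/n when a
single sample carries all expression, and undefined (NaN here) when mu = 0.
This is the population (uncorrected) estimator — no n/(n-1) bias factor —
which is the one the trapezoidal Lorenz-area definition corresponds to.

A "Gini gene" is a gene in the low tail of the Gini distribution: either the
bottom-N genes (N matched to a benchmark list size) or the genes at or below
a low percentile (typically the 20th) of the defined Gini values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneList

__all__ = [
    "gini_coefficient",
    "matrix_gini",
    "lorenz_curve",
    "LorenzCurve",
    "gini_profile",
    "GiniGeneSelection",
    "select_gini_genes",
    "gc_to_percentiles",
    "benchmark_coverage",
]


def _validate_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D expression vector")
    if x.size < 2:
        raise ValueError("Gini coefficient needs at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("expression values must be finite")
    if np.any(x < 0):
        raise ValueError("expression values must be nonnegative")
    return x


def gini_coefficient(x) -> float:
    """Gini coefficient of a nonnegative vector; NaN when the mean is zero.

    Computed from the sorted vector as
    ``G = 2 * sum_i i*x_(i) / (n * sum x) - (n+1)/n`` (i ranked ascending
    from 1), which is algebraically identical to the pairwise
    mean-absolute-difference form and to the trapezoidal Lorenz-area ratio.
    """
    x = _validate_vector(x)
    n = x.size
    xs = np.sort(x)  # summing the sorted vector keeps the result permutation-exact
    total = xs.sum()
    if total == 0:
        return float("nan")
    ranks = np.arange(1, n + 1)
    return float(2.0 * (ranks * xs).sum() / (n * total) - (n + 1) / n)


def matrix_gini(values: np.ndarray) -> np.ndarray:
    """Row-wise Gini coefficients of a nonnegative matrix; NaN for zero rows."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("expected a genes x samples matrix with >= 2 samples")
    n = v.shape[1]
    xs = np.sort(v, axis=1)
    totals = xs.sum(axis=1)
    ranks = np.arange(1, n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * (xs * ranks).sum(axis=1) / (n * totals) - (n + 1) / n
    g[totals == 0] = np.nan
    return g


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative sample fraction vs cumulative expression fraction.

    Both arrays start at 0, end at 1, and are nondecreasing; the value
    fraction never exceeds the population fraction (the curve lies under the
    line of equality).
    """

    cum_population_fraction: np.ndarray
    cum_value_fraction: np.ndarray

    def gini(self) -> float:
        """Area-ratio Gini: 1 minus twice the trapezoidal area under the curve."""
        area = np.trapezoid(self.cum_value_fraction, self.cum_population_fraction)
        return float(1.0 - 2.0 * area)


def lorenz_curve(x) -> LorenzCurve:
    """Lorenz curve of a nonnegative vector with positive mean.

    Samples are sorted ascending; the curve is anchored at (0, 0).
    """
    x = _validate_vector(x)
    total = x.sum()
    if total == 0:
        raise ValueError("Lorenz curve undefined for an all-zero vector (mean = 0)")
    xs = np.sort(x)
    n = xs.size
    pop = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    val = np.concatenate([[0.0], np.cumsum(xs) / total])
    return LorenzCurve(cum_population_fraction=pop, cum_value_fraction=val)


def gini_profile(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene Gini profile of an expression matrix.

    Returns a DataFrame indexed by gene ID with columns ``gc`` (NaN when the
    gene is all-zero), ``n_samples``, ``mean_expr``, ``median_expr`` and
    ``zero_total``. All-zero genes are retained and flagged, never dropped:
    downstream selection and statistics decide how to treat them.
    """
    if m.n_samples < 2:
        raise ValueError("Gini profile needs at least 2 samples")
    gc = matrix_gini(m.values)
    return pd.DataFrame(
        {
            "gc": gc,
            "n_samples": m.n_samples,
            "mean_expr": m.values.mean(axis=1),
            "median_expr": np.median(m.values, axis=1),
            "zero_total": np.isnan(gc),
        },
        index=pd.Index(m.gene_ids, name="gene_id"),
    )


@dataclass(frozen=True)
class GiniGeneSelection:
    """A Gini-gene set plus the rule and cutoff that produced it."""

    method: str  # "bottom_n" | "bottom_percentile"
    threshold: float
    selected: GeneList
    cutoff_gc: float


def _defined(profiles: pd.DataFrame) -> pd.DataFrame:
    return profiles[profiles["gc"].notna()]


def select_gini_genes(profiles: pd.DataFrame, method: str, threshold) -> GiniGeneSelection:
    """Select Gini genes by bottom-N or bottom-percentile rule.

    Genes with undefined (all-zero) Gini are excluded before ranking.
    ``bottom_n`` returns exactly N genes, breaking ties at the cutoff by
    ascending gene ID. ``bottom_percentile`` returns every gene at or below
    the linear-interpolation percentile of the defined Gini values, ties
    included.
    """
    defined = _defined(profiles)
    if defined.empty:
        raise ValueError("no genes with defined Gini coefficient")
    method = method.lower()
    if method == "bottom_n":
        n = int(threshold)
        if n < 1 or n > len(defined):
            raise ValueError(
                f"bottom_n threshold {n} outside [1, {len(defined)} defined genes]"
            )
        order = np.lexsort((defined.index.to_numpy(), defined["gc"].to_numpy()))
        chosen = defined.iloc[order[:n]]
        cutoff = float(chosen["gc"].max())
        selected = GeneList(frozenset(chosen.index), label=f"bottom_{n}")
    elif method == "bottom_percentile":
        p = float(threshold)
        if not 0 < p < 100:
            raise ValueError("percentile must lie in (0, 100)")
        cutoff = float(np.percentile(defined["gc"].to_numpy(), p))
        chosen = defined[defined["gc"] <= cutoff]
        selected = GeneList(frozenset(chosen.index), label=f"bottom_{p:g}pct")
    else:
        raise ValueError(f"unknown selection method: {method!r}")
    return GiniGeneSelection(method=method, threshold=float(threshold), selected=selected, cutoff_gc=cutoff)


def gc_to_percentiles(profiles: pd.DataFrame) -> pd.Series:
    """Convert Gini coefficients to ascending percentiles in (0, 100].

    percentile(g) = average rank of g's Gini (ties averaged) divided by the
    number of defined genes, times 100. Undefined-Gini genes get NaN.
    """
    defined = _defined(profiles)
    if defined.empty:
        raise ValueError("no genes with defined Gini coefficient")
    ranks = rankdata(defined["gc"].to_numpy(), method="average")
    pct = pd.Series(ranks / len(defined) * 100.0, index=defined.index, name="gc_percentile")
    return pct.reindex(profiles.index)


def benchmark_coverage(selection, benchmark: GeneList, universe: GeneList) -> float:
    """Fraction of benchmark genes (within the universe) captured by a selection.

    ``|selected ∩ benchmark ∩ universe| / |benchmark ∩ universe|``.
    """
    selected = selection.selected.genes if isinstance(selection, GiniGeneSelection) else frozenset(selection)
    bench_in_universe = benchmark.genes & universe.genes
    if not bench_in_universe:
        raise ValueError("benchmark has no genes in the universe")
    return len(selected & bench_in_universe) / len(bench_in_universe)
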