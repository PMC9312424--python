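import numpy as np
import pandas as pd
import pytest

from ginigenes import ExpressionMatrix, GeneList, Unit


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 4 samples: constant, single-spike, all-zero, mixed rows."""
    values = np.array(
        [
            [5.0, 5.0, 5.0, 5.0],
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [1.0, 2.0, 3.0, 4.0],
        ]
    )
    return ExpressionMatrix(
        gene_ids=["const", "spike", "zero", "mixed"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=values,
        unit=Unit.RAW,
    )


@pytest.fixture
def profiles_10() -> pd.DataFrame:
    """10 genes with distinct Gini values 0.1..1.0 and median expression."""
    gc = np.arange(1, 11) / 10.0
    return pd.DataFrame(
        {
            "gc": gc,
            "n_samples": 10,
            "mean_expr": np.linspace(100, 10, 10),
            "median_expr": np.linspace(100, 10, 10),
            "zero_total": False,
        },
        index=pd.Index([f"g{i}" for i in range(10)], name="gene_id"),
    )


def gini_pairwise_oracle(x) -> float:
    """Brute-force mean-absolute-difference Gini: sum_ij |xi-xj| / (2 n^2 mu)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mu = x.mean()
    if mu == 0:
        return float("nan")
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * mu))


def bh_stepup_oracle(p):
    """Hand implementation of the BH step-up rule."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@pytest.fixture
def benchmark_list() -> GeneList:
    return GeneList(frozenset({"g0", "g1", "g2"}), label="benchmark")
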