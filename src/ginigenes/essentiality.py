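"""Essentiality classes and their relationship to expression stability.

Whole-animal RNAi phenotypes with six independent replicate treatments per
gene are classified as:

* ``G1`` high-confidence essential — arrested in >= 5 of 6 replicates
* ``G2`` medium-confidence essential — arrested in 3 or 4 of 6
* ``G3`` wild-type — arrested in <= 2 of 6
* ``G4`` unknown — no usable worm population could be generated
* ``G5`` untested — no RNAi clone or other technical limitation

The stability comparison asks whether a class's Gini coefficients are lower
than the rest of the tested genes, with three complementary tests: a
left-tailed Wilcoxon rank-sum, a two-sample Kolmogorov-Smirnov test, and an
exact one-sided binomial sign test of falling below the overall median Gini.
Genes with Gini exactly 0 are excluded from the sign test (a zero Gini in
sparse single-cell data usually reflects detection in a single aggregate,
not genuine stability); an optional flag applies the same exclusion to the
Wilcoxon/KS tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import wilcoxon_rank_sum_less

__all__ = [
    "CLASSES",
    "classify_rnai_phenotypes",
    "essentiality_table_from_counts",
    "read_essentiality_table",
    "sign_test_below_median",
    "GroupComparison",
    "compare_gc_by_group",
]

CLASSES = ("G1", "G2", "G3", "G4", "G5")


def classify_rnai_phenotypes(
    arrested_reps,
    tested_reps: int = 6,
    *,
    population_generated: bool = True,
    tested: bool = True,
) -> str:
    """Classify a gene's RNAi outcome into G1..G5.

    ``arrested_reps`` is the number of replicate treatments (out of
    ``tested_reps``) in which animals arrested. Untested genes are G5; tested
    genes for which no scorable population could be generated (missing count)
    are G4.
    """
    if not tested:
        return "G5"
    if arrested_reps is None or (isinstance(arrested_reps, float) and np.isnan(arrested_reps)):
        if population_generated:
            raise ValueError("missing arrest count for a gene flagged as having a scorable population")
        return "G4"
    arrested = int(arrested_reps)
    if not 0 <= arrested <= tested_reps:
        raise ValueError(f"arrested_reps {arrested} outside [0, {tested_reps}]")
    if arrested >= 5:
        return "G1"
    if arrested >= 3:
        return "G2"
    return "G3"


def essentiality_table_from_counts(counts: pd.DataFrame, tested_reps: int = 6) -> pd.DataFrame:
    """Build a classed essentiality table from per-gene arrest counts.

    ``counts`` is indexed by gene ID with an ``arrested_reps`` column;
    optional boolean columns ``population_generated`` and ``tested`` route
    genes to G4/G5. Returns a DataFrame with ``arrested_reps``,
    ``tested_reps`` and ``class`` columns.
    """
    pop = counts.get("population_generated", pd.Series(True, index=counts.index))
    tst = counts.get("tested", pd.Series(True, index=counts.index))
    classes = [
        classify_rnai_phenotypes(
            a if not (isinstance(a, float) and np.isnan(a)) else None,
            tested_reps,
            population_generated=bool(p),
            tested=bool(t),
        )
        for a, p, t in zip(counts["arrested_reps"], pop, tst)
    ]
    out = pd.DataFrame(
        {
            "arrested_reps": counts["arrested_reps"],
            "tested_reps": tested_reps,
            "class": classes,
        },
        index=counts.index,
    )
    out.index.name = "gene_id"
    return out


def read_essentiality_table(path) -> pd.DataFrame:
    """Read an essentiality TSV: ``gene_id`` plus ``class`` or ``arrested_reps``.

    With an ``arrested_reps`` column and no ``class`` column, classes are
    derived with :func:`classify_rnai_phenotypes`.
    """
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0)
    frame.index = frame.index.astype(str)
    if "class" in frame.columns:
        bad = set(frame["class"].astype(str)) - set(CLASSES) - {"ESSENTIAL", "NONESSENTIAL"}
        if bad:
            raise ValueError(f"{path}: unknown essentiality classes {sorted(bad)}")
        frame["class"] = frame["class"].astype(str)
        return frame
    if "arrested_reps" not in frame.columns:
        raise ValueError(f"{path}: need a 'class' or 'arrested_reps' column")
    return essentiality_table_from_counts(frame)


def sign_test_below_median(group_gc, overall_median: float) -> float:
    """Exact one-sided sign test that a group's Gini sits below a reference median.

    Values equal to the median are dropped; with k of the remaining m values
    below the median, p = P(Binomial(m, 1/2) >= k).
    """
    gc = np.asarray(group_gc, dtype=float)
    gc = gc[~np.isnan(gc)]
    gc = gc[gc != overall_median]
    m = gc.size
    if m == 0:
        raise ValueError("no group values distinct from the overall median")
    k = int((gc < overall_median).sum())
    return float(sps.binomtest(k, m, 0.5, alternative="greater").pvalue)


@dataclass(frozen=True)
class GroupComparison:
    """Stability comparison of one essentiality group against the rest."""

    group_label: str
    n_group: int
    n_group_gc_positive: int
    wilcoxon_p: float
    ks_p: float
    sign_test_p: float


def compare_gc_by_group(
    profiles: pd.DataFrame,
    table: pd.DataFrame,
    group_classes: Iterable[str],
    *,
    exclude_zero_gc: bool = False,
) -> GroupComparison:
    """Compare one class group's Gini coefficients to all other tested genes.

    The group is every gene whose class is in ``group_classes``; the
    complement is every other gene in ``table`` — both restricted to genes
    with a defined Gini in ``profiles``. The sign test always excludes
    zero-Gini genes and uses the overall median over all defined (or, with
    ``exclude_zero_gc``, all positive) Gini values; ``exclude_zero_gc=True``
    extends the zero exclusion to the Wilcoxon and KS tests too.
    """
    group_classes = sorted(set(group_classes))
    unknown = set(group_classes) - set(CLASSES) - {"ESSENTIAL", "NONESSENTIAL"}
    if unknown:
        raise ValueError(f"unknown classes: {sorted(unknown)}")
    shared = table.index.intersection(profiles.index)
    gc = profiles.loc[shared, "gc"]
    cls = table.loc[shared, "class"]
    defined = gc.notna()
    gc, cls = gc[defined], cls[defined]
    in_group = cls.isin(group_classes)
    n_group = int(in_group.sum())
    n_positive = int((gc[in_group] > 0).sum())

    gc_rank = gc[gc > 0] if exclude_zero_gc else gc
    grp = gc_rank[cls.reindex(gc_rank.index).isin(group_classes)].to_numpy()
    rest = gc_rank[~cls.reindex(gc_rank.index).isin(group_classes)].to_numpy()
    if grp.size < 2 or rest.size < 2:
        raise ValueError("group or complement has fewer than 2 genes with usable Gini")
    wilcoxon_p = wilcoxon_rank_sum_less(grp, rest)
    ks_p = float(sps.ks_2samp(grp, rest).pvalue)

    positive = gc[gc > 0]
    overall_median = float(positive.median())
    group_positive = positive[cls.reindex(positive.index).isin(group_classes)].to_numpy()
    if group_positive.size and np.all(group_positive == overall_median):
        sign_p = 1.0  # every value ties the median: the sign test carries no evidence
    else:
        sign_p = sign_test_below_median(group_positive, overall_median)
    return GroupComparison(
        group_label="+".join(group_classes),
        n_group=n_group,
        n_group_gc_positive=n_positive,
        wilcoxon_p=wilcoxon_p,
        ks_p=ks_p,
        sign_test_p=sign_p,
    )
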