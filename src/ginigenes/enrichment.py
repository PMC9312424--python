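"""GO over/under-representation of gene sets with a compounded background.

The test is the hypergeometric tail: with a universe of N genes of which K
are annotated to a term, a query of n genes containing k annotated ones has
over-representation p-value P(X >= k) and under-representation p-value
P(X <= k), X ~ Hypergeometric(N, K, n). P-values are corrected across terms
by the Benjamini-Hochberg step-up rule and a term is called enriched at
q < 0.05.

The compounded background mirrors the two-pass design used for comparing
enrichment across datasets of very different sizes: a first pass enriches
each dataset's selection against its full universe; the union of terms
over-represented in at least one dataset becomes the shared term background,
and second-pass analyses are restricted to those terms (and, optionally, to
genes annotated by at least one of them) so that term frequencies are
comparable across datasets.

Annotations are consumed either as GAF 2.x (columns 2, 5 and 9: object ID,
GO ID, aspect) or as a two-column TSV of (term_id, gene_id). Analyses here
use direct gene-to-term annotations without ontology-graph propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneList

__all__ = [
    "AnnotationSet",
    "read_annotations",
    "bh_fdr",
    "hypergeometric_enrichment",
    "build_background",
    "background_universe",
    "term_coverage_profile",
    "compare_term_sets",
    "coverage_correlation",
]

ASPECTS = {"BP", "MF", "CC"}
_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


@dataclass(frozen=True)
class AnnotationSet:
    """Term -> gene-set mapping restricted to a single GO aspect.

    ``background_terms``, when set, restricts which terms participate in
    enrichment (the compounded background of :func:`build_background`).
    """

    term_to_genes: Mapping[str, frozenset]
    aspect: str = "BP"
    background_terms: frozenset | None = None

    def __post_init__(self):
        if self.aspect not in ASPECTS:
            raise ValueError(f"aspect must be one of {sorted(ASPECTS)}")
        clean = {}
        for term, genes in self.term_to_genes.items():
            genes = frozenset(str(g) for g in genes)
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            clean[str(term)] = genes
        object.__setattr__(self, "term_to_genes", clean)
        if self.background_terms is not None:
            object.__setattr__(self, "background_terms", frozenset(map(str, self.background_terms)))

    @property
    def terms(self) -> list:
        return sorted(self.term_to_genes)

    def active_terms(self) -> list:
        """Terms participating in enrichment: the background if set, else all."""
        if self.background_terms is None:
            return self.terms
        return sorted(t for t in self.term_to_genes if t in self.background_terms)

    def annotated_genes(self, terms: Iterable[str] | None = None) -> frozenset:
        use = self.term_to_genes if terms is None else {t: self.term_to_genes[t] for t in terms if t in self.term_to_genes}
        out: set = set()
        for genes in use.values():
            out |= genes
        return frozenset(out)

    def with_background(self, terms: Iterable[str]) -> "AnnotationSet":
        return replace(self, background_terms=frozenset(map(str, terms)))


def read_annotations(path, format: str = "auto", aspect: str = "BP") -> AnnotationSet:
    """Read annotations from GAF 2.x or a two-column (term_id, gene_id) TSV.

    ``format="auto"`` treats files whose first data line has >= 15 columns
    (or a ``!gaf-version`` header) as GAF. Only rows of the requested aspect
    are kept for GAF input.
    """
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    fmt = format.lower()
    if fmt == "auto":
        data = [l for l in lines if not l.startswith(("!", "#"))]
        is_gaf = any(l.startswith("!gaf-version") for l in lines) or (
            data and len(data[0].split("\t")) >= 15
        )
        fmt = "gaf" if is_gaf else "tsv"
    mapping: dict = {}
    if fmt == "gaf":
        want = {k for k, v in _GAF_ASPECT.items() if v == aspect}
        for line in lines:
            if line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: GAF line with fewer than 9 columns")
            gene, term, asp = cols[1], cols[4], cols[8]
            if asp in want:
                mapping.setdefault(term, set()).add(gene)
    elif fmt == "tsv":
        start = 0
        first = lines[0].split("\t")
        if first and not first[0].upper().startswith("GO:") and first[0].lower() in {"term_id", "term", "go_id"}:
            start = 1
        for line in lines[start:]:
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}: annotation TSV needs 2 columns (term_id, gene_id)")
            mapping.setdefault(cols[0], set()).add(cols[1])
    else:
        raise ValueError(f"unknown annotation format: {format!r}")
    return AnnotationSet({t: frozenset(g) for t, g in mapping.items()}, aspect=aspect)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1; monotone in the p-value
    ranks and never below the raw p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    query: GeneList,
    universe: GeneList,
    annotations: AnnotationSet,
    direction: str = "over",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of ``query`` within ``universe``.

    Annotation gene sets are intersected with the universe; terms that end up
    with no universe genes are skipped. BH correction runs across all tested
    terms (the annotation set's active background). Returns a DataFrame
    indexed by term with columns ``k_hits``, ``K_universe``, ``n_query``,
    ``N_universe``, ``p_raw``, ``q_bh``, ``direction``, ``enriched`` and
    ``coverage`` (= k/K).
    """
    direction = direction.lower()
    if direction not in {"over", "under"}:
        raise ValueError("direction must be 'over' or 'under'")
    uni = universe.genes
    qry = query.genes
    if not qry <= uni:
        extra = sorted(qry - uni)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {extra}")
    N, n = len(uni), len(qry)
    rows = []
    for term in annotations.active_terms():
        term_genes = annotations.term_to_genes[term] & uni
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & qry)
        if direction == "over":
            p = float(hypergeom.sf(k - 1, N, K, n))
        else:
            p = float(hypergeom.cdf(k, N, K, n))
        rows.append((term, k, K, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term_id", "k_hits", "K_universe", "p_raw"]).set_index("term_id")
    table["n_query"] = n
    table["N_universe"] = N
    table["q_bh"] = bh_fdr(table["p_raw"].to_numpy()) if len(table) else []
    table["direction"] = direction
    table["enriched"] = table["q_bh"] < alpha
    table["coverage"] = table["k_hits"] / table["K_universe"]
    return table[
        ["k_hits", "K_universe", "n_query", "N_universe", "p_raw", "q_bh", "direction", "enriched", "coverage"]
    ]


def build_background(
    annotations: AnnotationSet,
    universes: Sequence[GeneList],
    selections: Sequence[GeneList],
    alpha: float = 0.05,
) -> AnnotationSet:
    """Compounded-background construction across datasets.

    First pass: each selection is tested for over-representation against its
    own full universe with all annotated terms. The background is the union
    of terms enriched (q < ``alpha``) in at least one dataset. If no term is
    enriched anywhere, the background falls back to all annotated terms with
    a warning. Returns the annotation set with ``background_terms`` set.
    """
    if len(universes) != len(selections):
        raise ValueError("need one universe per selection")
    first_pass = annotations.with_background(annotations.terms) if annotations.background_terms else annotations
    background: set = set()
    for universe, selection in zip(universes, selections):
        table = hypergeometric_enrichment(selection, universe, first_pass, direction="over", alpha=alpha)
        background |= set(table.index[table["enriched"]])
    if not background:
        warnings.warn(
            "first-pass enrichment found no enriched terms; background falls back to all annotated terms",
            stacklevel=2,
        )
        background = set(annotations.terms)
    return annotations.with_background(background)


def background_universe(annotations: AnnotationSet, universe: GeneList) -> GeneList:
    """Universe genes annotated by at least one background term."""
    annotated = annotations.annotated_genes(annotations.active_terms())
    return GeneList(universe.genes & annotated, label=f"{universe.label}|background-annotated")


def term_coverage_profile(table: pd.DataFrame) -> pd.Series:
    """Coverage k/K for every tested term (enriched or not)."""
    return table["coverage"].rename("coverage")


def compare_term_sets(tables: Mapping[str, pd.DataFrame], groups: Mapping[str, Sequence[str]]) -> tuple:
    """Common and group-exclusive enriched terms across datasets.

    ``common`` = terms enriched in every table. For each group, ``exclusive``
    = terms enriched in at least one of its tables and in none of the tables
    of any other group. Returns ``(common, {group: term set})``.
    """
    for gname, members in groups.items():
        if not members:
            raise ValueError(f"group {gname!r} has no datasets")
        unknown = [m for m in members if m not in tables]
        if unknown:
            raise ValueError(f"group {gname!r} names unknown datasets: {unknown}")
    enriched = {label: set(t.index[t["enriched"]]) for label, t in tables.items()}
    common = set.intersection(*enriched.values()) if enriched else set()
    exclusive = {}
    for gname, members in groups.items():
        inside = set().union(*(enriched[m] for m in members))
        others = [m for g2, mm in groups.items() if g2 != gname for m in mm]
        outside = set().union(*(enriched[m] for m in others)) if others else set()
        exclusive[gname] = inside - outside
    return common, exclusive


def coverage_correlation(profile_a: pd.Series, profile_b: pd.Series) -> float:
    """Spearman correlation of two term-coverage profiles on shared terms."""
    from scipy.stats import spearmanr

    shared = profile_a.index.intersection(profile_b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared terms")
    a = profile_a.loc[shared].to_numpy(dtype=float)
    b = profile_b.loc[shared].to_numpy(dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant coverage vector: correlation undefined", stacklevel=2)
        return float("nan")
    return float(spearmanr(a, b).statistic)
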