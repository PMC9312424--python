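"""Cross-species comparison of expression stability on 1:1 orthologs.

Per-organism Gini profiles are aligned through a 1:1 ortholog map into a
genes x organisms Gini matrix. "Gini genes" for the comparison are the union
of each organism's bottom 20th-percentile genes. Organisms are compared by
the Spearman correlation of their Gini vectors, clustered by average linkage
on 1 - rho, and embedded by PCA (organisms as variables, genes as
observations, columns mean-centered and unscaled). The genes driving the
leading component are summarized as the top/middle/bottom-k PC1 score lists:
with clades separating along PC1, the extremes are clade-specific stable
genes and the middle genes are shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .io import OrthologMap

__all__ = [
    "build_ortholog_gc_matrix",
    "union_gini_genes",
    "spearman_matrix",
    "cluster_organisms",
    "linkage_to_newick",
    "pca_gc",
    "PCAResult",
    "extreme_loading_genes",
    "CrossSpeciesResult",
    "analyze_cross_species",
]


def build_ortholog_gc_matrix(
    profiles_per_organism: Mapping[str, pd.DataFrame],
    ortholog_map: OrthologMap,
) -> pd.DataFrame:
    """Align per-organism Gini profiles into a genes x organisms matrix.

    Only 1:1 ortholog rows are used; a row is kept when every organism has
    that gene with a defined Gini. Returns a DataFrame indexed by the
    ortholog-map row index, one column per organism.
    """
    missing = [o for o in ortholog_map.organisms if o not in profiles_per_organism]
    if missing:
        raise KeyError(f"no Gini profiles for organisms: {missing}")
    rows = ortholog_map.one_to_one_rows()
    cols = {}
    keep = pd.Series(True, index=rows.index)
    for org in ortholog_map.organisms:
        gc = profiles_per_organism[org]["gc"]
        mapped = rows[org].map(gc)
        keep &= mapped.notna()
        cols[org] = mapped
    matrix = pd.DataFrame(cols).loc[keep]
    matrix.index.name = "ortholog_id"
    return matrix


def union_gini_genes(matrix: pd.DataFrame, percentile: float = 20.0) -> tuple:
    """Rows that are bottom-percentile Gini genes in at least one organism.

    Returns ``(subset, per_organism_counts)`` where counts report how many of
    the union rows are Gini genes in each organism (the bar-plot data next to
    the dendrogram).
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    cutoffs = matrix.quantile(percentile / 100.0, axis=0, interpolation="linear")
    is_gini = matrix.le(cutoffs, axis=1)
    union = is_gini.any(axis=1)
    subset = matrix.loc[union]
    counts = is_gini.loc[union].sum(axis=0).rename("n_gini_genes")
    return subset, counts


def spearman_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations between organism Gini vectors."""
    if len(matrix) < 3:
        raise ValueError("need at least 3 ortholog rows")
    orgs = list(matrix.columns)
    vals = matrix.to_numpy(dtype=float)
    constant = [o for i, o in enumerate(orgs) if np.all(vals[:, i] == vals[0, i])]
    if constant:
        import warnings

        warnings.warn(f"constant Gini column(s) {constant}: correlations undefined", stacklevel=2)
    if len(orgs) == 2:
        rho = spearmanr(vals[:, 0], vals[:, 1]).statistic
        corr = np.array([[1.0, rho], [rho, 1.0]])
    else:
        corr = spearmanr(vals).statistic
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    for i, o in enumerate(orgs):
        if o in constant:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
            corr[i, i] = 1.0
    return pd.DataFrame(corr, index=orgs, columns=orgs)


def cluster_organisms(spearman: pd.DataFrame) -> tuple:
    """Average-linkage clustering of organisms on distance 1 - rho.

    Returns ``(linkage_matrix, newick)``. Ties in merge order are resolved by
    scipy's index-order convention, which with the label-sorted input below
    is deterministic by label order. NaN correlations are an error.
    """
    if spearman.isna().any().any():
        raise ValueError("correlation matrix contains undefined entries")
    labels = list(spearman.columns)
    dist = 1.0 - spearman.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, linkage_to_newick(Z, labels)


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string.

    Branch lengths follow the ultrametric convention: a node at merge height
    h sits at depth h/2, so a child's branch length is (h_parent - h_child)/2.
    """
    tree = to_tree(Z)

    def height(node):
        return 0.0 if node.is_leaf() else node.dist

    def rec(node, parent_height):
        bl = (parent_height - height(node)) / 2.0
        if node.is_leaf():
            return f"{labels[node.id]}:{bl:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{bl:.10g}"

    left = rec(tree.left, tree.dist)
    right = rec(tree.right, tree.dist)
    return f"({left},{right});"


@dataclass(frozen=True)
class PCAResult:
    """Scores (genes x components), loadings (organisms x components), variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_var: np.ndarray


def pca_gc(matrix: pd.DataFrame) -> PCAResult:
    """PCA of the Gini matrix with organisms as variables.

    Columns are mean-centered but not scaled (Gini coefficients already live
    on [0, 1]). Components come from the eigendecomposition of the covariance
    via SVD; each component's sign is fixed so its largest-|loading| entry is
    positive. ``scores @ loadings.T`` reconstructs the centered matrix.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 organisms")
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 ortholog rows")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component is positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    var = S**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    comps = [f"PC{j + 1}" for j in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=comps),
        explained_var=explained,
    )


def extreme_loading_genes(scores: pd.DataFrame, component: int = 1, k: int = 20) -> tuple:
    """Top-k, middle-k and bottom-k genes by a principal-component score.

    Rows are ranked by the chosen component's score (ties broken by row ID);
    top = largest k, bottom = smallest k, middle = the k rows straddling the
    median rank. Requires ``k <= n_rows / 3`` so the three windows exist.
    """
    col = f"PC{component}"
    if col not in scores.columns:
        raise ValueError(f"no component {col} in scores")
    n = len(scores)
    if k < 1 or k > n / 3:
        raise ValueError(f"k={k} must satisfy 1 <= k <= n_rows/3 = {n / 3:g}")
    vals = scores[col].to_numpy()
    ids = scores.index.to_numpy()
    order = np.lexsort((ids, vals))  # ascending score, ties by row ID
    sorted_ids = ids[order]
    bottom = list(sorted_ids[:k])
    top = list(sorted_ids[-k:][::-1])
    start = (n - k) // 2
    middle = list(sorted_ids[start : start + k])
    return top, middle, bottom


@dataclass(frozen=True)
class CrossSpeciesResult:
    """Bundle of every cross-species output for one analysis run."""

    organisms: list
    gc_matrix: pd.DataFrame
    gini_gene_matrix: pd.DataFrame
    gini_gene_counts: pd.Series
    spearman: pd.DataFrame
    linkage: np.ndarray
    newick: str
    pca: PCAResult
    top_genes: list
    middle_genes: list
    bottom_genes: list


def analyze_cross_species(
    profiles_per_organism: Mapping[str, pd.DataFrame],
    ortholog_map: OrthologMap,
    percentile: float = 20.0,
    k_extreme: int = 20,
    pca_on_union: bool = True,
) -> CrossSpeciesResult:
    """Full cross-species analysis: align, select, correlate, cluster, embed."""
    gc_matrix = build_ortholog_gc_matrix(profiles_per_organism, ortholog_map)
    union, counts = union_gini_genes(gc_matrix, percentile=percentile)
    corr = spearman_matrix(union)
    Z, newick = cluster_organisms(corr)
    pca = pca_gc(union if pca_on_union else gc_matrix)
    k = min(k_extreme, len(pca.scores) // 3)
    top, middle, bottom = extreme_loading_genes(pca.scores, component=1, k=max(k, 1))
    return CrossSpeciesResult(
        organisms=list(gc_matrix.columns),
        gc_matrix=gc_matrix,
        gini_gene_matrix=union,
        gini_gene_counts=counts,
        spearman=corr,
        linkage=Z,
        newick=newick,
        pca=pca,
        top_genes=top,
        middle_genes=middle,
        bottom_genes=bottom,
    )
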