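"""Ortholog alignment, union Gini genes, clustering, PCA, extreme loadings."""

import numpy as np
import pandas as pd
import pytest

from ginigenes import (
    OrthologMap,
    build_ortholog_gc_matrix,
    cluster_organisms,
    extreme_loading_genes,
    pca_gc,
    spearman_matrix,
    union_gini_genes,
)


def _omap(rows, organisms):
    table = pd.DataFrame(rows, columns=organisms)
    table.index = pd.Index([f"og{i}" for i in range(len(table))], name="ortholog_id")
    return OrthologMap(table=table, one_to_one=pd.Series(True, index=table.index))


def _profiles(mapping):
    return pd.DataFrame({"gc": pd.Series(mapping, dtype=float)})


class TestBuildMatrix:
    def test_two_organisms_three_rows(self):
        omap = _omap([["a1", "b1"], ["a2", "b2"], ["a3", "b3"]], ["orgA", "orgB"])
        profs = {
            "orgA": _profiles({"a1": 0.1, "a2": 0.2, "a3": 0.3}),
            "orgB": _profiles({"b1": 0.4, "b2": 0.5, "b3": 0.6}),
        }
        mat = build_ortholog_gc_matrix(profs, omap)
        assert mat.shape == (3, 2)
        np.testing.assert_allclose(mat["orgA"], [0.1, 0.2, 0.3])

    def test_undefined_gc_row_dropped(self):
        omap = _omap([["a1", "b1"], ["a2", "b2"]], ["orgA", "orgB"])
        profs = {
            "orgA": _profiles({"a1": 0.1, "a2": np.nan}),
            "orgB": _profiles({"b1": 0.4, "b2": 0.5}),
        }
        mat = build_ortholog_gc_matrix(profs, omap)
        assert list(mat.index) == ["og0"]

    def test_non_one_to_one_rows_excluded(self):
        table = pd.DataFrame([["a1", "b1"], ["a2", "b2"]], columns=["orgA", "orgB"])
        omap = OrthologMap(table=table, one_to_one=pd.Series([True, False]))
        profs = {
            "orgA": _profiles({"a1": 0.1, "a2": 0.2}),
            "orgB": _profiles({"b1": 0.3, "b2": 0.4}),
        }
        assert len(build_ortholog_gc_matrix(profs, omap)) == 1

    def test_missing_organism_is_key_error(self):
        omap = _omap([["a1", "b1"]], ["orgA", "orgB"])
        with pytest.raises(KeyError):
            build_ortholog_gc_matrix({"orgA": _profiles({"a1": 0.1})}, omap)


class TestUnionGiniGenes:
    def test_identical_columns_same_set(self):
        gc = np.linspace(0.01, 0.99, 50)
        mat = pd.DataFrame({"a": gc, "b": gc}, index=[f"og{i}" for i in range(50)])
        subset, counts = union_gini_genes(mat, percentile=20)
        single = mat[mat["a"] <= np.percentile(gc, 20)]
        assert set(subset.index) == set(single.index)
        assert counts["a"] == counts["b"] == len(subset)

    def test_disjoint_bottom_sets_union(self):
        n = 50
        a = np.arange(n, dtype=float)
        b = a[::-1].copy()  # bottom-20% sets of a and b are disjoint
        mat = pd.DataFrame({"a": a, "b": b}, index=[f"og{i:02d}" for i in range(n)])
        subset, _ = union_gini_genes(mat, percentile=20)
        bottom_a = set(mat.index[a <= np.percentile(a, 20)])
        bottom_b = set(mat.index[b <= np.percentile(b, 20)])
        assert set(subset.index) == bottom_a | bottom_b
        assert bottom_a.isdisjoint(bottom_b)

    def test_percentile_bounds_and_identity(self):
        mat = pd.DataFrame({"a": [0.1, 0.2], "b": [0.3, 0.4]})
        with pytest.raises(ValueError):
            union_gini_genes(mat, percentile=0)
        with pytest.raises(ValueError):
            union_gini_genes(mat, percentile=101)
        subset, _ = union_gini_genes(mat, percentile=100)
        assert len(subset) == len(mat)


class TestSpearmanMatrix:
    def test_duplicated_columns_give_unit_offdiagonal(self):
        rng = np.random.default_rng(1)
        gc = rng.random(30)
        mat = pd.DataFrame({"a": gc, "b": gc, "c": rng.random(30)})
        corr = spearman_matrix(mat)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)

    def test_rank_reverse_gives_minus_one(self):
        gc = np.linspace(0.1, 0.9, 20)
        corr = spearman_matrix(pd.DataFrame({"a": gc, "b": gc[::-1]}))
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(40):
            mat = pd.DataFrame(rng.random((1000, 2)), columns=["a", "b"])
            hits += abs(spearman_matrix(mat).loc["a", "b"]) < 0.1
        assert hits >= 36

    def test_constant_column_flagged(self):
        mat = pd.DataFrame({"a": [0.2, 0.2, 0.2], "b": [0.1, 0.5, 0.9]})
        with pytest.warns(UserWarning):
            corr = spearman_matrix(mat)
        assert np.isnan(corr.loc["a", "b"])


class TestClustering:
    def test_identical_pair_merges_first(self):
        rng = np.random.default_rng(3)
        gc = rng.random(40)
        mat = pd.DataFrame({"a": gc, "b": gc, "c": rng.random(40)})
        corr = spearman_matrix(mat)
        Z, newick = cluster_organisms(corr)
        first = {int(Z[0, 0]), int(Z[0, 1])}
        assert first == {0, 1}  # columns a and b
        assert "(a:0,b:0)" in newick

    def test_equal_distances_caterpillar_by_label_order(self):
        labels = ["a", "b", "c", "d"]
        corr = pd.DataFrame(0.5 * np.ones((4, 4)), index=labels, columns=labels)
        np.fill_diagonal(corr.values, 1.0)
        Z, newick = cluster_organisms(corr)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert {int(Z[1, 0]), int(Z[1, 1])} == {2, 4}  # c joins the (a,b) cluster

    def test_nan_rejected(self):
        corr = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_organisms(corr)

    def test_newick_parses_with_all_leaves(self):
        import io as _io

        from Bio import Phylo

        labels = ["w", "x", "y", "z"]
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.random((50, 4)), columns=labels)
        _, newick = cluster_organisms(spearman_matrix(mat))
        tree = Phylo.read(_io.StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == labels


class TestPca:
    def test_rank_one_two_correlated_organisms(self):
        rng = np.random.default_rng(5)
        a = rng.random(100)
        res = pca_gc(pd.DataFrame({"a": a, "b": 2 * a + 0.1}))
        np.testing.assert_allclose(res.explained_var, [1.0, 0.0], atol=1e-12)

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(6)
        res = pca_gc(pd.DataFrame(rng.random((200, 5)), columns=list("abcde")))
        assert res.explained_var.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.explained_var) <= 1e-12)

    def test_reconstruction(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.random((60, 4)), columns=list("abcd"))
        res = pca_gc(mat)
        centered = mat.to_numpy() - mat.to_numpy().mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centered, atol=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(8)
        res = pca_gc(pd.DataFrame(rng.random((80, 4)), columns=list("abcd")))
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pca_gc(pd.DataFrame({"a": [0.1, 0.2], "b": [0.2, 0.3]}))


class TestExtremeLoadingGenes:
    def test_three_rows_k1(self):
        scores = pd.DataFrame({"PC1": [3.0, 1.0, 2.0]}, index=["hi", "lo", "mid"])
        top, middle, bottom = extreme_loading_genes(scores, k=1)
        assert top == ["hi"] and middle == ["mid"] and bottom == ["lo"]

    def test_symmetric_scores_middle_is_zero(self):
        scores = pd.DataFrame({"PC1": [-2.0, -1.0, 0.0, 1.0, 2.0]}, index=list("abcde"))
        _, middle, _ = extreme_loading_genes(scores, k=1)
        assert middle == ["c"]

    def test_duplicate_scores_tie_broken_by_row_id(self):
        scores = pd.DataFrame({"PC1": [1.0, 1.0, 0.0, 2.0, 2.0, 3.0]},
                              index=["b", "a", "z", "d", "c", "e"])
        top, _, bottom = extreme_loading_genes(scores, k=2)
        assert top == ["e", "d"]  # 3.0 then tie (c, d) -> d ranks above c descending
        assert bottom == ["z", "a"]  # 0.0 then tie (a, b) -> a first ascending

    def test_k_too_large_rejected(self):
        scores = pd.DataFrame({"PC1": [1.0, 2.0, 3.0]}, index=list("abc"))
        with pytest.raises(ValueError):
            extreme_loading_genes(scores, k=2)
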