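"""Hypergeometric enrichment, BH FDR, compounded background, term-set algebra."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from ginigenes import (
    AnnotationSet,
    GeneList,
    bh_fdr,
    build_background,
    compare_term_sets,
    coverage_correlation,
    hypergeometric_enrichment,
    read_annotations,
    term_coverage_profile,
)

from conftest import bh_stepup_oracle


def _universe(n):
    return GeneList(frozenset(f"g{i:02d}" for i in range(n)), "universe")


def _enrich_one_term(N, K, n, k, direction):
    """Run enrichment on one synthetic term with exact counts (N, K, n, k)."""
    genes = [f"g{i:02d}" for i in range(N)]
    term_genes = frozenset(genes[:K])
    # query: k annotated genes + (n - k) unannotated ones
    query = frozenset(genes[:k]) | frozenset(genes[K : K + n - k])
    ann = AnnotationSet({"T": term_genes}, aspect="BP")
    table = hypergeometric_enrichment(
        GeneList(query, "q"), GeneList(frozenset(genes), "u"), ann, direction=direction
    )
    return float(table.loc["T", "p_raw"])


def _tail_by_enumeration(N, K, n, k, direction):
    """Exact tail probability by enumerating all C(N, n) query draws.

    Items 0..K-1 are annotated; a draw with j of them has probability
    C(K, j) C(N-K, n-j) / C(N, n). Sum the relevant tail.
    """
    total = comb(N, n)
    js = range(k, min(K, n) + 1) if direction == "over" else range(0, k + 1)
    return sum(comb(K, j) * comb(N - K, n - j) for j in js) / total


class TestHypergeometricTails:
    @pytest.mark.parametrize(
        "N,K,n,k,direction,expected",
        [
            (10, 4, 5, 4, "over", 6 / 252),  # exact tail enumeration
            (10, 4, 5, 0, "under", 6 / 252),  # C(6,5)/C(10,5)
        ],
    )
    def test_hand_cases(self, N, K, n, k, direction, expected):
        assert _enrich_one_term(N, K, n, k, direction) == pytest.approx(expected, rel=1e-12)

    def test_saturated_over_representation_p_is_one(self):
        # K = n = N and k at its maximum
        assert _enrich_one_term(6, 6, 6, 6, "over") == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_all_small_configs(self):
        for N in range(2, 13):
            for n in range(1, N + 1):
                for K in range(1, N + 1):
                    for k in range(max(0, n - (N - K)), min(K, n) + 1):
                        for direction in ("over", "under"):
                            p = _enrich_one_term(N, K, n, k, direction)
                            oracle = _tail_by_enumeration(N, K, n, k, direction)
                            assert p == pytest.approx(oracle, rel=1e-10), (N, K, n, k, direction)

    def test_query_outside_universe_rejected(self):
        ann = AnnotationSet({"T": frozenset({"g00"})}, aspect="BP")
        with pytest.raises(ValueError):
            hypergeometric_enrichment(
                GeneList(frozenset({"zz"}), "q"), _universe(5), ann
            )

    def test_term_with_no_universe_genes_skipped(self):
        ann = AnnotationSet({"T": frozenset({"zz"}), "S": frozenset({"g00"})}, aspect="BP")
        table = hypergeometric_enrichment(
            GeneList(frozenset({"g00"}), "q"), _universe(5), ann
        )
        assert list(table.index) == ["S"]


class TestBhFdr:
    def test_hand_stepup_case(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_capped(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            m = int(rng.integers(1, 120))
            p = rng.random(m) ** rng.uniform(0.3, 3.0)
            q = bh_fdr(p)
            np.testing.assert_allclose(q, bh_stepup_oracle(p), rtol=1e-12)
            # monotone in p-rank, >= raw p, <= 1
            order = np.argsort(p, kind="mergesort")
            assert np.all(np.diff(q[order]) >= -1e-15)
            assert np.all(q >= p - 1e-15) and np.all(q <= 1.0 + 1e-15)


class TestBuildBackground:
    def _setup(self, seed=0, planted_frac=0.8):
        """Universe of 200 genes, one planted term on the query, several nulls."""
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(200)]
        query = frozenset(genes[:40])
        planted = frozenset(genes[:20]) | frozenset(rng.choice(genes[40:], 5, replace=False))
        nulls = {
            f"N{t}": frozenset(rng.choice(genes, 20, replace=False)) for t in range(5)
        }
        ann = AnnotationSet({"PLANTED": planted, **nulls}, aspect="BP")
        return ann, GeneList(frozenset(genes), "u"), GeneList(query, "q")

    def test_planted_term_lands_in_background(self):
        ann, uni, query = self._setup()
        bg = build_background(ann, [uni], [query])
        assert "PLANTED" in bg.background_terms

    def test_no_signal_falls_back_to_all_terms_with_warning(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i:03d}" for i in range(100)]
        ann = AnnotationSet(
            {f"N{t}": frozenset(rng.choice(genes, 10, replace=False)) for t in range(4)},
            aspect="BP",
        )
        uni = GeneList(frozenset(genes), "u")
        query = GeneList(frozenset(rng.choice(genes, 20, replace=False)), "q")
        with pytest.warns(UserWarning):
            bg = build_background(ann, [uni], [query])
        assert bg.background_terms == frozenset(ann.terms)

    def test_union_across_datasets(self):
        # dataset A plants T1, dataset B plants T2 -> background is {T1, T2}
        genes = [f"g{i:03d}" for i in range(300)]
        qa = frozenset(genes[:30])
        qb = frozenset(genes[100:130])
        ann = AnnotationSet(
            {"T1": frozenset(genes[:25]), "T2": frozenset(genes[100:125])}, aspect="BP"
        )
        uni = GeneList(frozenset(genes), "u")
        bg = build_background(ann, [uni, uni], [GeneList(qa, "a"), GeneList(qb, "b")])
        assert bg.background_terms == {"T1", "T2"}


class TestCoverageAndTermSets:
    def test_coverage_ratio(self):
        genes = [f"g{i:02d}" for i in range(20)]
        ann = AnnotationSet({"T": frozenset(genes[:8])}, aspect="BP")
        table = hypergeometric_enrichment(
            GeneList(frozenset(genes[:2]), "q"), GeneList(frozenset(genes), "u"), ann
        )
        cov = term_coverage_profile(table)
        assert cov["T"] == pytest.approx(2 / 8)

    def test_full_coverage(self):
        genes = [f"g{i:02d}" for i in range(10)]
        ann = AnnotationSet({"T": frozenset(genes[:4])}, aspect="BP")
        table = hypergeometric_enrichment(
            GeneList(frozenset(genes[:4]), "q"), GeneList(frozenset(genes), "u"), ann
        )
        assert term_coverage_profile(table)["T"] == 1.0

    def test_conservation_hits_bounded_by_annotations(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i:03d}" for i in range(100)]
        ann = AnnotationSet(
            {f"T{t}": frozenset(rng.choice(genes, 15, replace=False)) for t in range(10)},
            aspect="BP",
        )
        query = GeneList(frozenset(rng.choice(genes, 30, replace=False)), "q")
        table = hypergeometric_enrichment(query, GeneList(frozenset(genes), "u"), ann)
        assert (table["k_hits"] <= table[["K_universe", "n_query"]].min(axis=1)).all()
        assert table["coverage"].between(0, 1).all()

    def test_identical_coverage_profiles_correlate_perfectly(self):
        cov = pd.Series([0.1, 0.5, 0.9, 0.3], index=list("ABCD"))
        assert coverage_correlation(cov, cov) == pytest.approx(1.0)
        assert coverage_correlation(cov, 1 - cov) == pytest.approx(-1.0)

    def test_replicate_queries_correlate(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i:03d}" for i in range(400)]
        stable = frozenset(genes[:100])
        ann = AnnotationSet(
            {
                **{f"P{t}": frozenset(rng.choice(sorted(stable), 40, replace=False)) for t in range(10)},
                **{f"N{t}": frozenset(rng.choice(genes, 40, replace=False)) for t in range(10)},
            },
            aspect="BP",
        )
        uni = GeneList(frozenset(genes), "u")
        covs = []
        for _ in range(2):  # two noisy replicates of the same stable-gene query
            q = set(rng.choice(sorted(stable), 90, replace=False))
            q |= set(rng.choice(genes, 5, replace=False))
            table = hypergeometric_enrichment(GeneList(frozenset(q), "q"), uni, ann)
            covs.append(term_coverage_profile(table))
        assert coverage_correlation(covs[0], covs[1]) > 0.8

    def test_common_and_exclusive_sets(self):
        def table(enriched_terms):
            idx = ["T1", "T2", "T3"]
            return pd.DataFrame({"enriched": [t in enriched_terms for t in idx]}, index=idx)

        tables = {"a": table({"T1", "T2"}), "b": table({"T2", "T3"})}
        common, exclusive = compare_term_sets(tables, {"A": ["a"], "B": ["b"]})
        assert common == {"T2"}
        assert exclusive == {"A": {"T1"}, "B": {"T3"}}

    def test_identical_tables_no_exclusives(self):
        t = pd.DataFrame({"enriched": [True, False]}, index=["T1", "T2"])
        common, exclusive = compare_term_sets({"a": t, "b": t.copy()}, {"A": ["a"], "B": ["b"]})
        assert common == {"T1"} and exclusive == {"A": set(), "B": set()}

    def test_empty_group_rejected(self):
        t = pd.DataFrame({"enriched": [True]}, index=["T1"])
        with pytest.raises(ValueError):
            compare_term_sets({"a": t}, {"A": ["a"], "B": []})


class TestAnnotationIO:
    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("GO:0000001\tga\nGO:0000001\tgb\nGO:0000002\tgc\n")
        ann = read_annotations(p)
        assert ann.term_to_genes["GO:0000001"] == {"ga", "gb"}
        assert ann.aspect == "BP"

    def test_gaf_aspect_filter(self, tmp_path):
        cols = ["DB", "{gene}", "SYM", "", "{term}", "REF", "IEA", "", "{aspect}"] + [""] * 8
        lines = ["!gaf-version: 2.2"]
        for gene, term, aspect in [
            ("ga", "GO:1", "P"),
            ("gb", "GO:1", "P"),
            ("gc", "GO:2", "F"),
        ]:
            lines.append(
                "\t".join(c.format(gene=gene, term=term, aspect=aspect) for c in cols)
            )
        p = tmp_path / "ann.gaf"
        p.write_text("\n".join(lines) + "\n")
        ann = read_annotations(p, aspect="BP")
        assert set(ann.terms) == {"GO:1"}
        assert ann.term_to_genes["GO:1"] == {"ga", "gb"}
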