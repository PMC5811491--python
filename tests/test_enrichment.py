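"""Hypergeometric/EASE tails, BH adjustment, enrichment runs and the
two-disease comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comorbnet.catalog import GeneSet
from comorbnet.enrichment import (
    AnnotationCollection,
    AnnotationTerm,
    bh_adjust,
    compare_enrichments,
    ease_pvalue,
    hypergeometric_pvalue,
    pathway_gene_breakdown,
    read_gmt,
    run_enrichment,
    write_gmt,
)
from comorbnet.errors import (
    EmptyIntersectionError,
    InvalidCountError,
    MalformedRecordError,
    UnknownTermError,
)
from comorbnet.synthetic import generate_annotations, generate_universe

from conftest import enumeration_tail, stepup_bh


class TestGmtIO:
    def test_read_computes_union_universe(self, tmp_path):
        path = tmp_path / "c.gmt"
        path.write_text("T1\tone\ta\tb\tc\nT2\ttwo\tc\td\te\tf\n")
        coll = read_gmt(path)
        assert len(coll) == 2
        assert coll.universe == {"A", "B", "C", "D", "E", "F"}

    def test_short_line_raises_with_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("T1\tonly-two-fields\n")
        with pytest.raises(MalformedRecordError, match="bad.gmt:1"):
            read_gmt(path)

    def test_duplicate_term_id_raises(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("T1\tx\ta\tb\nT1\ty\tc\td\n")
        with pytest.raises(MalformedRecordError, match="duplicate"):
            read_gmt(path)

    def test_round_trip_preserves_member_sets(self, tmp_path):
        universe = generate_universe(200)
        coll = generate_annotations(universe, 50, (3, 10), seed=11)
        out = tmp_path / "rt.gmt"
        write_gmt(coll, out)
        back = read_gmt(out, universe=universe)
        assert {t.term_id: t.members for t in back.terms} == {
            t.term_id: t.members for t in coll.terms
        }


class TestHypergeometricTail:
    @pytest.mark.parametrize(
        "k,n,K,N,expected",
        [
            (0, 5, 4, 10, 1.0),          # P(X >= 0) is certain
            (4, 5, 4, 10, 6 / 252),      # all 4 term genes drawn: C(6,1)/C(10,5)
            (1, 1, 3, 10, 0.3),          # single draw: K/N
            (5, 5, 5, 5, 1.0),           # n = K = N: single-point mass
        ],
    )
    def test_frozen_values_match_enumeration(self, k, n, K, N, expected):
        assert hypergeometric_pvalue(k, n, K, N) == pytest.approx(expected, abs=1e-12)
        assert float(enumeration_tail(k, n, K, N)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "k,n,K,N", [(-1, 2, 2, 4), (3, 2, 5, 6), (2, 7, 3, 6), (1, 2, 8, 6)]
    )
    def test_invalid_margins_raise(self, k, n, K, N):
        with pytest.raises(InvalidCountError):
            hypergeometric_pvalue(k, n, K, N)

    def test_stable_at_large_universe(self):
        # 15k-node interactome-scale margins stay in (0, 1] without underflow to 0
        p = hypergeometric_pvalue(40, 300, 60, 15000)
        assert 0 < p < 1e-30


class TestEase:
    def test_single_gene_overlap_is_never_significant(self):
        assert ease_pvalue(1, 1, 3, 10) == 1.0

    def test_matches_enumeration_with_overlap_reduced_by_one(self):
        assert ease_pvalue(4, 5, 4, 10) == pytest.approx(
            float(enumeration_tail(3, 5, 4, 10)), abs=1e-12
        )

    def test_requires_positive_overlap(self):
        with pytest.raises(InvalidCountError):
            ease_pvalue(0, 5, 4, 10)

    def test_at_least_as_conservative_as_standard_tail(self):
        for N in range(2, 9):
            for n in range(1, N + 1):
                for K in range(1, N + 1):
                    for k in range(1, min(n, K) + 1):
                        assert ease_pvalue(k, n, K, N) >= hypergeometric_pvalue(k, n, K, N)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_frozen_examples(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(InvalidCountError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(InvalidCountError):
            bh_adjust([0.0, 0.5])

    @given(
        pvals=st.lists(
            st.floats(min_value=1e-12, max_value=1.0, allow_nan=False), min_size=1, max_size=50
        )
    )
    def test_matches_stepup_definition_and_bounds(self, pvals):
        adjusted = bh_adjust(pvals)
        assert adjusted == pytest.approx(stepup_bh(pvals), rel=1e-12)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-15)
        assert np.all(adjusted <= 1.0 + 1e-15)


class TestRunEnrichment:
    def test_full_term_membership_has_minimal_p(self, small_collection):
        gs = GeneSet(name="t1-full", members=small_collection["T1"].members)
        results = run_enrichment(gs, small_collection, alpha=0.05, min_overlap=1)
        assert results[0].term_id == "T1"
        assert results[0].p == min(r.p for r in results)

    def test_term_order_invariance(self, small_collection):
        gs = GeneSet(name="g", members=frozenset({"A1", "A2", "B1", "C1"}))
        reversed_coll = AnnotationCollection(
            "pathway", list(reversed(small_collection.terms)), small_collection.universe
        )
        res_fwd = run_enrichment(gs, small_collection, min_overlap=1)
        res_rev = run_enrichment(gs, reversed_coll, min_overlap=1)
        assert [(r.term_id, r.p, r.p_bh) for r in res_fwd] == [
            (r.term_id, r.p, r.p_bh) for r in res_rev
        ]

    def test_no_mapped_gene_raises(self, small_collection):
        gs = GeneSet(name="alien", members=frozenset({"ZZZ"}))
        with pytest.raises(EmptyIntersectionError):
            run_enrichment(gs, small_collection)

    def test_min_overlap_gates_bh_family(self, small_collection):
        gs = GeneSet(name="g", members=frozenset({"A1", "A2", "B1"}))
        tested = run_enrichment(gs, small_collection, min_overlap=2)
        assert {r.term_id for r in tested} == {"T1"}

    def test_significant_count_monotone_in_alpha(self):
        universe = generate_universe(500)
        coll = generate_annotations(universe, 40, (5, 20), seed=3)
        gs = GeneSet(name="g", members=coll.terms[0].members | coll.terms[1].members)
        counts = []
        for alpha in (0.001, 0.01, 0.05, 0.2):
            res = run_enrichment(gs, coll, alpha=alpha, min_overlap=1)
            counts.append(sum(r.significant for r in res))
        assert counts == sorted(counts)

    def test_removing_foreign_term_keeps_raw_p(self, small_collection):
        gs = GeneSet(name="g", members=frozenset({"A1", "A2", "A3"}))
        full = run_enrichment(gs, small_collection, min_overlap=1)
        pruned_coll = AnnotationCollection(
            "pathway",
            [t for t in small_collection.terms if t.term_id != "T2"],
            small_collection.universe,  # explicit universe held fixed
        )
        pruned = run_enrichment(gs, pruned_coll, min_overlap=1)
        p_full = {r.term_id: r.p for r in full}
        for r in pruned:
            assert r.p == p_full[r.term_id]


class TestCompareAndBreakdown:
    def test_identical_tables_all_shared(self, small_collection):
        gs = GeneSet(name="g", members=frozenset({"A1", "A2", "B1", "B2"}))
        res = run_enrichment(gs, small_collection, alpha=0.99, min_overlap=1)
        cmp = compare_enrichments(res, res)
        assert cmp.n_a_specific == cmp.n_b_specific == 0
        assert cmp.n_shared == sum(r.significant for r in res)

    def test_disjoint_significant_sets(self):
        def row(tid, sig):
            return type("R", (), dict(term_id=tid, term_name=tid, p=0.001, p_bh=0.005,
                                      significant=sig))()
        cmp = compare_enrichments([row("X", True)], [row("Y", True), row("X", False)])
        assert cmp.n_shared == 0 and cmp.n_a_specific == 1 and cmp.n_b_specific == 1

    def test_partition_counts_consistent(self, small_collection):
        gs_a = GeneSet(name="a", members=small_collection["T1"].members)
        gs_b = GeneSet(name="b", members=small_collection["T2"].members)
        res_a = run_enrichment(gs_a, small_collection, alpha=0.5, min_overlap=1)
        res_b = run_enrichment(gs_b, small_collection, alpha=0.5, min_overlap=1)
        cmp = compare_enrichments(res_a, res_b)
        assert cmp.n_shared + cmp.n_a_specific == sum(r.significant for r in res_a)
        assert cmp.n_shared + cmp.n_b_specific == sum(r.significant for r in res_b)

    def test_breakdown_partitions_term_members(self, small_collection):
        a = GeneSet(name="a", members=frozenset({"A1", "A2", "A4"}))
        b = GeneSet(name="b", members=frozenset({"A2", "A3"}))
        bd = pathway_gene_breakdown("T1", small_collection, a, b)
        union = bd.a_only_members | bd.b_only_members | bd.both_members | bd.unassigned_members
        assert union == small_collection["T1"].members
        assert bd.a_only_members == {"A1", "A4"}
        assert bd.b_only_members == {"A3"}
        assert bd.both_members == {"A2"}

    def test_breakdown_unknown_term(self, small_collection, set_a, set_b):
        with pytest.raises(UnknownTermError):
            pathway_gene_breakdown("NOPE", small_collection, set_a, set_b)

    def test_breakdown_matches_independent_scan(self):
        rng = np.random.default_rng(7)
        universe = [f"G{i}" for i in range(100)]
        term = frozenset(rng.choice(universe, 30, replace=False).tolist())
        coll = AnnotationCollection("pathway", [AnnotationTerm("T", "t", term)], universe)
        a = frozenset(rng.choice(universe, 40, replace=False).tolist())
        b = frozenset(rng.choice(universe, 40, replace=False).tolist())
        bd = pathway_gene_breakdown(
            "T", coll, GeneSet(name="a", members=a), GeneSet(name="b", members=b)
        )
        for g in term:  # brute-force membership scan
            expected = (
                "both" if g in a and g in b
                else "a" if g in a
                else "b" if g in b
                else "none"
            )
            observed = (
                "both" if g in bd.both_members
                else "a" if g in bd.a_only_members
                else "b" if g in bd.b_only_members
                else "none"
            )
            assert observed == expected
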