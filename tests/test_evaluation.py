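"""Sn/PPV/Acc, hypergeometric enrichment, BH correction, ORS."""

import itertools
from math import comb, sqrt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smile_ppi import (
    GeneSetCollection,
    accuracy,
    bh_adjust,
    enrich_modules,
    hypergeometric_p,
    match_matrix,
    matched_complex_fraction,
    ors,
    ppv,
    quality_report,
    sensitivity,
)


def _collection(**sets):
    return GeneSetCollection("ref", {k: frozenset(v) for k, v in sets.items()})


class TestMatchMatrix:
    def test_identical_single_set(self):
        m = match_matrix([{"a", "b", "c"}], _collection(r1={"a", "b", "c"}))
        assert m.t.tolist() == [[3]]
        assert m.v.tolist() == [3] and m.w.tolist() == [3]

    def test_disjoint_universes_all_zero(self):
        m = match_matrix([{"a"}, {"b"}], _collection(r1={"x"}, r2={"y"}))
        assert not m.t.any()

    def test_intersection_counts(self):
        m = match_matrix([{"A", "B", "C"}], _collection(r1={"B", "C", "D"}))
        assert m.t.tolist() == [[2]]

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            match_matrix([], _collection(r1={"a"}))


class TestSnPpvAcc:
    def test_perfect_prediction(self):
        ref = _collection(r1={"a", "b"}, r2={"c", "d"})
        m = match_matrix([{"a", "b"}, {"c", "d"}], ref)
        assert sensitivity(m) == 1.0
        assert ppv(m) == 1.0
        assert accuracy(sensitivity(m), ppv(m)) == 1.0

    def test_half_covered_reference(self):
        ref = _collection(r1={"a", "b", "c", "d", "e"}, r2={"v", "w", "x", "y", "z"})
        m = match_matrix([{"a", "b", "c", "d", "e"}], ref)
        assert sensitivity(m) == 0.5

    def test_ppv_split_hits(self):
        ref = _collection(r1={"a", "b", "c"}, r2={"d"})
        m = match_matrix([{"a", "b", "c", "d"}], ref)
        assert ppv(m) == 0.75

    def test_all_zero_matrix_ppv_warns(self):
        m = match_matrix([{"a"}], _collection(r1={"x"}))
        assert sensitivity(m) == 0.0
        with pytest.warns(UserWarning, match="denominator"):
            assert ppv(m) == 0.0

    def test_three_by_three_hand_computed(self):
        predicted = [{"a", "b", "c"}, {"c", "d"}, {"e", "f", "g", "h"}]
        ref = _collection(
            r1={"a", "b"}, r2={"c", "d", "e"}, r3={"f", "g", "h", "i"}
        )
        m = match_matrix(predicted, ref)
        # t = [[2,1,0],[0,2,0],[0,1,3]]
        assert m.t.tolist() == [[2, 1, 0], [0, 2, 0], [0, 1, 3]]
        assert sensitivity(m) == pytest.approx((2 + 2 + 3) / (2 + 3 + 4))
        assert ppv(m) == pytest.approx((2 + 2 + 3) / 9)
        assert accuracy(sensitivity(m), ppv(m)) == pytest.approx(
            sqrt((7 / 9) * (7 / 9))
        )

    @pytest.mark.parametrize(
        "sn, p, expected", [(1, 1, 1.0), (0, 0.8, 0.0), (0.5, 0.75, sqrt(0.375))]
    )
    def test_accuracy_geometric_mean(self, sn, p, expected):
        assert accuracy(sn, p) == pytest.approx(expected)

    @given(st.data())
    def test_acc_squared_identity(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 1000)))
        universe = [f"p{i}" for i in range(12)]
        predicted = [
            set(rng.choice(universe, size=rng.integers(1, 6), replace=False))
            for _ in range(3)
        ]
        ref = {
            f"r{i}": set(rng.choice(universe, size=rng.integers(1, 6), replace=False))
            for i in range(3)
        }
        m = match_matrix(predicted, _collection(**ref))
        sn = sensitivity(m)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = ppv(m)
        acc = accuracy(sn, p)
        assert acc**2 == pytest.approx(sn * p)
        assert 0 <= sn <= 1 and 0 <= p <= 1 and 0 <= acc <= 1


def _hypergeom_enumerated(N, n, T, t):
    """Brute-force oracle: enumerate all C(N, n) draws, count those with at
    least t of the first T elements."""
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for x in draw if x < T) >= t
    )
    return hits / comb(N, n)


class TestHypergeometric:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_p(100, 10, 20, 0) == 1.0

    def test_exact_small_case(self):
        assert hypergeometric_p(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_fully_annotated_universe(self):
        assert hypergeometric_p(30, 7, 30, 5) == pytest.approx(1.0)

    @pytest.mark.parametrize("N", [5, 8, 10])
    def test_matches_enumeration(self, N):
        for n in range(1, N + 1):
            for T in range(0, N + 1):
                for t in range(0, min(n, T) + 1):
                    assert hypergeometric_p(N, n, T, t) == pytest.approx(
                        _hypergeom_enumerated(N, n, T, t), abs=1e-12
                    )

    def test_non_increasing_in_t(self):
        values = [hypergeometric_p(50, 10, 15, t) for t in range(0, 11)]
        assert values == sorted(values, reverse=True)

    @pytest.mark.parametrize(
        "args", [(10, 11, 5, 0), (10, 5, 11, 0), (10, 5, 5, 6), (10, 5, 2, 3)]
    )
    def test_invalid_configurations_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeometric_p(*args)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == [0.04]

    def test_step_up_hand_computation(self):
        # ranks 1..3: 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_adjusted_at_least_raw_and_clipped(self):
        raw = [0.001, 0.5, 0.9, 0.99]
        adjusted = bh_adjust(raw)
        assert all(a >= r for a, r in zip(adjusted, raw))
        assert all(a <= 1.0 for a in adjusted)

    def test_permutation_invariance(self):
        raw = [0.04, 0.001, 0.3, 0.02, 0.8]
        adjusted = dict(zip(raw, bh_adjust(raw)))
        perm = [0.3, 0.8, 0.04, 0.001, 0.02]
        assert [adjusted[p] for p in perm] == pytest.approx(bh_adjust(perm))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestEnrichment:
    PATHWAYS = _collection(
        path_a={f"a{i}" for i in range(10)},
        path_b={f"b{i}" for i in range(10)},
    )

    def test_module_matching_pathway_is_significant(self):
        modules = {"m1": {f"a{i}" for i in range(10)}}
        results = enrich_modules(modules, self.PATHWAYS, background=1000)
        by_pathway = {r.pathway_id: r for r in results}
        assert by_pathway["path_a"].significant
        assert by_pathway["path_a"].p < 1e-10

    def test_zero_overlap_not_significant(self):
        modules = {"m1": {f"z{i}" for i in range(10)}}
        results = enrich_modules(modules, self.PATHWAYS, background=1000)
        assert all(r.p == 1.0 and not r.significant for r in results)

    def test_bh_family_spans_all_pairs(self):
        modules = {
            "m1": {f"a{i}" for i in range(10)},
            "m2": {f"z{i}" for i in range(10)},
        }
        results = enrich_modules(modules, self.PATHWAYS, background=1000)
        assert len(results) == 4
        assert all(r.p_adjusted >= r.p for r in results)

    def test_member_outside_universe_dropped_with_warning(self):
        universe = {f"a{i}" for i in range(10)} | {f"u{i}" for i in range(90)}
        modules = {"m1": {"a0", "a1", "ghost"}}
        with pytest.warns(UserWarning, match="outside the background"):
            results = enrich_modules(modules, self.PATHWAYS, background=universe)
        assert results[0].overlap == 2

    def test_integer_background(self):
        modules = {"m1": {"a0", "a1"}}
        results = enrich_modules(modules, self.PATHWAYS, background=100)
        expected = hypergeometric_p(100, 2, 10, 2)
        by_pathway = {r.pathway_id: r for r in results}
        assert by_pathway["path_a"].p == pytest.approx(expected)


class TestORS:
    def _results(self, flags):
        from smile_ppi.evaluate import EnrichmentResult

        return [
            EnrichmentResult(f"m{i}", "p", 1, 0.01, 0.01, flag)
            for i, flag in enumerate(flags)
        ]

    def test_all_significant(self):
        assert ors(self._results([True, True, True]), 3) == 1.0

    def test_none_significant(self):
        assert ors(self._results([False, False]), 2) == 0.0

    def test_counting(self):
        assert ors(self._results([True, True, False, False]), 4) == 0.5

    def test_order_invariant(self):
        results = self._results([True, False, True])
        assert ors(results, 3) == ors(list(reversed(results)), 3)


class TestMatchedFraction:
    REF = _collection(r1={"a", "b", "c", "d"}, r2={"w", "x", "y", "z"})

    def test_identical_modules(self):
        count, fraction = matched_complex_fraction(
            [{"a", "b", "c", "d"}, {"w", "x", "y", "z"}], self.REF
        )
        assert (count, fraction) == (2, 1.0)

    def test_disjoint_modules(self):
        count, fraction = matched_complex_fraction([{"q1", "q2"}], self.REF)
        assert (count, fraction) == (0, 0.0)

    def test_partial_counting(self):
        modules = [{"a", "b", "c", "d"}] * 3 + [{"q1", "q2"}] * 7
        count, fraction = matched_complex_fraction(modules, self.REF, 0.25)
        assert (count, fraction) == (3, pytest.approx(0.3))

    def test_empty_module_list_rejected(self):
        with pytest.raises(ValueError):
            matched_complex_fraction([], self.REF)


class TestQualityReport:
    def test_composite_is_sum_of_ors(self):
        modules = {
            "m1": {f"a{i}" for i in range(10)},
            "m2": {f"b{i}" for i in range(10)},
        }
        complexes = _collection(r1={f"a{i}" for i in range(10)})
        resources = {
            "res1": _collection(p1={f"a{i}" for i in range(10)}),
            "res2": _collection(p2={f"b{i}" for i in range(10)}),
        }
        background = {f"a{i}" for i in range(10)} | {f"b{i}" for i in range(10)} | {
            f"u{i}" for i in range(200)
        }
        report = quality_report(modules, complexes, resources, background)
        assert report.composite == pytest.approx(sum(report.ors_by_resource.values()))
        assert report.ors_by_resource == {"res1": 0.5, "res2": 0.5}
        assert report.acc == pytest.approx(sqrt(report.sn * report.ppv))
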