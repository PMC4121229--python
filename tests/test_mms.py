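from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from apoutlier import (NO_SIGNAL, IndexedSeries, VerdictKind, complement,
                       mms_classify, mms_max, mms_min, mms_scores)
from conftest import make_ap
from _oracles import oracle_mms, oracle_mms_classify


class TestPublishedScores:
    @pytest.mark.parametrize("key,expected_max,expected_min", [
        (2, 0.401, 0.399),
        (3, 0.945, 0.254),
        (4, 0.399, 0.401),
        (5, 0.254, 0.945),
    ])
    def test_demonstration_series(self, table_series, key, expected_max,
                                  expected_min):
        s = table_series[key]
        assert round(mms_max(s), 3) == expected_max
        assert round(mms_min(s), 3) == expected_min

    def test_bad_detection_scores(self, interior_outlier_series):
        # the interior outlier drags the *min*-side score above threshold
        assert round(mms_max(interior_outlier_series), 3) == 0.377
        assert mms_min(interior_outlier_series) == pytest.approx(4 / 9.4)

    def test_constant_series_is_no_signal(self):
        s = IndexedSeries.from_values([5.0] * 4)
        pair = mms_scores(s)
        assert pair.score_max is NO_SIGNAL and pair.score_min is NO_SIGNAL


class TestClassification:
    def test_max_outlier_flagged(self, table_series):
        v = mms_classify(table_series[3], r_w=0.4)
        assert v.kind is VerdictKind.MAX_OUTLIER and v.position == 4

    def test_bad_detection_flags_minimum(self, interior_outlier_series):
        # documented failure mode: interior outlier implicates the wrong extreme
        v = mms_classify(interior_outlier_series, r_w=0.4)
        assert v.kind is VerdictKind.MIN_OUTLIER and v.position == 0

    def test_exact_ap_not_flagged(self, ap_factory):
        assert not mms_classify(ap_factory(5, 100.0, 1.0), r_w=0.4)

    def test_threshold_equality_not_flagged(self, ap_factory):
        # an AP scores exactly 2/n; equality means consistent with the border
        s = ap_factory(5, 0.0, 2.0)
        assert mms_classify(s, r_w=mms_max(s)).kind is VerdictKind.NONE

    def test_earliest_extreme_wins_ties(self):
        s = IndexedSeries.from_values([0.0, 9.0, 1.0, 9.0, 0.5])
        assert mms_classify(s, r_w=0.1).position == 1

    def test_max_preferred_on_exact_score_tie(self):
        # symmetric series: both scores equal; deterministic max preference
        s = IndexedSeries.from_values([-5.0, 0.0, 0.0, 0.0, 5.0])
        pair = mms_scores(s)
        assert pair.score_max == pytest.approx(pair.score_min)
        assert mms_classify(s, r_w=0.3).kind is VerdictKind.MAX_OUTLIER


class TestScoreProperties:
    @given(n=st.integers(2, 200), a1=st.floats(-100, 100),
           d=st.floats(0.01, 10), sign=st.sampled_from([-1.0, 1.0]))
    @settings(derandomize=True, max_examples=200)
    def test_any_nonconstant_ap_scores_two_over_n(self, n, a1, d, sign):
        s = make_ap(n, a1, sign * d)
        assert mms_max(s) == pytest.approx(2 / n, rel=1e-12)
        assert mms_min(s) == pytest.approx(2 / n, rel=1e-12)

    @given(values=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
           alpha=st.floats(0.01, 100), beta=st.floats(-1e3, 1e3))
    @settings(derandomize=True, max_examples=200)
    def test_affine_invariance(self, values, alpha, beta):
        arr = np.asarray(values)
        assume(arr.max() - arr.min() > 1e-3 * (1 + np.abs(arr).max())
               or arr.max() == arr.min())
        s = IndexedSeries.from_values(values)
        t = IndexedSeries.from_values(alpha * np.asarray(values) + beta)
        a, b = mms_scores(s), mms_scores(t)
        if a.score_max is NO_SIGNAL:
            assert b.score_max is NO_SIGNAL
            return
        assert b.score_max == pytest.approx(a.score_max, rel=1e-6)
        assert b.score_min == pytest.approx(a.score_min, rel=1e-6)

    @given(values=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_negative_scale_swaps_scores(self, values):
        s = IndexedSeries.from_values(values)
        t = IndexedSeries.from_values(-np.asarray(values))
        a, b = mms_scores(s), mms_scores(t)
        if a.score_max is NO_SIGNAL:
            assert b.score_max is NO_SIGNAL
            return
        assert b.score_max == pytest.approx(a.score_min, rel=1e-9)
        assert b.score_min == pytest.approx(a.score_max, rel=1e-9)

    @given(values=st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_complement_duality(self, values):
        s = IndexedSeries.from_values(values)
        a = mms_scores(s)
        c = mms_scores(complement(s))
        if a.score_max is NO_SIGNAL:
            assert c.score_max is NO_SIGNAL
            return
        assert a.score_min == pytest.approx(c.score_max, rel=1e-9)
        assert a.score_max == pytest.approx(c.score_min, rel=1e-9)

    @given(values=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    @settings(derandomize=True, max_examples=200)
    def test_scores_within_unit_interval(self, values):
        pair = mms_scores(IndexedSeries.from_values(values))
        if pair.score_max is NO_SIGNAL:
            return
        assert 0 < pair.score_max <= 1 + 1e-12
        assert 0 < pair.score_min <= 1 + 1e-12


class TestOracleEquivalence:
    def test_exhaustive_length5_grid(self):
        """Classification agrees with literal rational-arithmetic scoring on
        every length-5 series over a small integer grid."""
        grid = (0, 1, 3, 7)
        r_w = Fraction(2, 5)
        checked = 0
        for values in product(grid, repeat=5):
            s = IndexedSeries.from_values(np.array(values, dtype=float))
            verdict = mms_classify(s, float(r_w))
            expected = oracle_mms_classify(values, r_w)
            if expected == "none":
                assert verdict.kind is VerdictKind.NONE, values
            else:
                side, pos = expected
                assert verdict.kind is (VerdictKind.MAX_OUTLIER if side == "max"
                                        else VerdictKind.MIN_OUTLIER), values
                assert verdict.position == pos, values
            smax, smin = oracle_mms(values)
            if smax is not None:
                pair = mms_scores(s)
                assert pair.score_max == pytest.approx(float(smax), rel=1e-12)
                assert pair.score_min == pytest.approx(float(smin), rel=1e-12)
            checked += 1
        assert checked == len(grid) ** 5
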