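import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apoutlier import (IndexedSeries, RemovalLedger, ZeroIndexSumError,
                       angular_shift_value, compact_after_removals,
                       constant_transform)
from _oracles import oracle_angular_shift, oracle_constant_transform


class TestAngularShiftValue:
    @pytest.mark.parametrize("ref,val,old,new,expected", [
        (0.0, 10.0, 5, 4, 8.0),          # one removal upstream
        (100.0, 102.0, 2, 1, 101.0),     # stays on the line y = 100 + x
        (3.0, 11.0, 4, 4, 11.0),         # no removals: identity
    ])
    def test_direct_cases(self, ref, val, old, new, expected):
        assert angular_shift_value(ref, val, old, new) == expected

    def test_collapse_onto_reference_rejected(self):
        with pytest.raises(ValueError):
            angular_shift_value(0.0, 1.0, 3, 0)

    def test_offset_beyond_original_rejected(self):
        with pytest.raises(ValueError):
            angular_shift_value(0.0, 1.0, 3, 4)

    @given(ref=st.integers(-50, 50), d=st.integers(-10, 10),
           old=st.integers(1, 30), new_frac=st.floats(0, 1))
    @settings(derandomize=True, max_examples=200)
    def test_collinearity_preserved_exactly(self, ref, d, old, new_frac):
        """A point on a line through the reference lands exactly on the same
        line at its new offset (integer line, exact arithmetic)."""
        new = max(1, round(new_frac * old))
        value = float(ref + d * old)
        assert angular_shift_value(float(ref), value, old, new) == ref + d * new

    @given(ref=st.floats(-100, 100), val=st.floats(-100, 100),
           old=st.integers(1, 40), new_frac=st.floats(0, 1))
    @settings(derandomize=True, max_examples=200)
    def test_matches_rational_oracle(self, ref, val, old, new_frac):
        new = max(1, round(new_frac * old))
        got = angular_shift_value(ref, val, old, new)
        assert got == pytest.approx(
            float(oracle_angular_shift(ref, val, old, new)), rel=1e-12, abs=1e-12)


class TestCompactAfterRemovals:
    def test_interior_removal_keeps_line(self):
        s = IndexedSeries.from_values([100.0, 101.0, 102.0, 103.0, 104.0])
        comp, orig = compact_after_removals(RemovalLedger(s, frozenset({2})))
        assert comp.indices.tolist() == [0, 1, 2, 3]
        assert comp.values.tolist() == [100.0, 101.0, 102.0, 103.0]
        assert orig.tolist() == [0, 1, 3, 4]

    def test_trailing_removal_shifts_nothing(self):
        s = IndexedSeries.from_values([100.0, 101.0, 102.0, 103.0, 204.0])
        comp, _ = compact_after_removals(RemovalLedger(s, frozenset({4})))
        assert comp.values.tolist() == [100.0, 101.0, 102.0, 103.0]

    def test_derived_offset_reduction(self):
        # element at offset 4 moves to offset 3: 0 + 40 * 3/4 = 30
        s = IndexedSeries.from_values([0.0, 10.0, 20.0, 31.0, 40.0])
        comp, _ = compact_after_removals(RemovalLedger(s, frozenset({3})))
        assert comp.values.tolist() == [0.0, 10.0, 20.0, 30.0]

    def test_initial_missing_treated_like_removals(self):
        # gap at position 2 of the line y = 100 + x
        s = IndexedSeries(np.array([0, 1, 3, 4]),
                          np.array([100.0, 101.0, 103.0, 104.0]))
        comp, _ = compact_after_removals(RemovalLedger(s))
        assert comp.values.tolist() == [100.0, 101.0, 102.0, 103.0]

    def test_elements_before_interior_reference_shift_symmetrically(self):
        s = IndexedSeries.from_values([0.0, 4.0, 8.0, 12.0, 16.0])
        ledger = RemovalLedger(s, frozenset({1}), reference_position=2)
        comp, orig = compact_after_removals(ledger)
        # survivors 0,2,3,4; point at old offset -2 moves to offset -1
        assert comp.values.tolist() == [4.0, 8.0, 12.0, 16.0]
        assert orig.tolist() == [0, 2, 3, 4]

    def test_reference_never_removable(self):
        s = IndexedSeries.from_values([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            RemovalLedger(s, frozenset(), reference_position=0).remove(0)

    @given(n=st.integers(5, 25),
           removals=st.sets(st.integers(1, 24), max_size=10),
           d=st.integers(-5, 5), a1=st.integers(-100, 100))
    @settings(derandomize=True, max_examples=150)
    def test_order_independence_and_collinearity(self, n, removals, d, a1):
        removals = {r for r in removals if r < n}
        if len(removals) > n - 2:
            return
        s = IndexedSeries.from_values(np.asarray(a1 + d * np.arange(n), float))
        ledger = RemovalLedger(s)
        for r in sorted(removals):
            ledger = ledger.remove(r)
        one_shot, _ = compact_after_removals(RemovalLedger(s, frozenset(removals)))
        stepwise, _ = compact_after_removals(ledger)
        # the compacted series is a pure function of the removed *set*
        assert one_shot.values.tolist() == stepwise.values.tolist()
        # collinear input stays exactly collinear after compaction
        expected = one_shot.values[0] + d * np.arange(one_shot.n)
        assert one_shot.values.tolist() == expected.tolist()


class TestConstantTransform:
    def test_published_transform_column(self, interior_outlier_series):
        got = constant_transform(interior_outlier_series)
        np.testing.assert_allclose(got, [0.0, 0.06, 0.12, 0.42, 0.24],
                                   atol=1e-12)

    @pytest.mark.parametrize("slope,intercept", [(2.0, 0.0), (-3.5, 7.0),
                                                 (0.0, 42.0)])
    def test_perfect_line_maps_to_zero(self, slope, intercept):
        s = IndexedSeries.from_values(intercept + slope * np.arange(6))
        np.testing.assert_array_equal(constant_transform(s), np.zeros(6))

    def test_line_with_gap_still_zero(self):
        # y = 2x sampled at x = 0,1,3,4
        s = IndexedSeries(np.array([0, 1, 3, 4]), np.array([0.0, 2.0, 6.0, 8.0]))
        np.testing.assert_array_equal(constant_transform(s), np.zeros(4))

    def test_reference_maps_to_zero_and_output_nonnegative(self):
        rng = np.random.default_rng(7)
        s = IndexedSeries.from_values(rng.normal(size=12))
        out = constant_transform(s)
        assert out[0] == 0.0
        assert (out >= 0).all()

    def test_zero_index_sum_rejected(self):
        s = IndexedSeries(np.array([0, 2, 4]), np.array([1.0, 2.0, 3.0]),
                          reference_position=2)
        with pytest.raises(ZeroIndexSumError):
            constant_transform(s)

    @given(values=st.lists(st.integers(-50, 50), min_size=3, max_size=20),
           c=st.integers(-10, 10), d=st.integers(-100, 100))
    @settings(derandomize=True, max_examples=200)
    def test_linear_trend_invariance(self, values, c, d):
        base = np.asarray(values, dtype=float)
        x = np.arange(base.size)
        s = IndexedSeries.from_values(base)
        t = IndexedSeries.from_values(base + c * x + d)
        np.testing.assert_allclose(constant_transform(t), constant_transform(s),
                                   rtol=1e-9, atol=1e-9)

    @given(values=st.lists(st.integers(-30, 30), min_size=3, max_size=12))
    @settings(derandomize=True, max_examples=200)
    def test_matches_rational_oracle(self, values):
        s = IndexedSeries.from_values(np.asarray(values, float))
        expected = [float(v) for v in
                    oracle_constant_transform(range(len(values)), values)]
        np.testing.assert_allclose(constant_transform(s), expected,
                                   rtol=1e-12, atol=1e-12)
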