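import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainrev import (
    TimeSeriesMatrix,
    fs_matrix,
    global_irreversibility,
    mutual_info_of_correlation,
    pairwise_irreversibility,
    reversibility_matrix,
    shifted_pearson,
    time_reverse,
)
from brainrev.core import FSMatrix
from brainrev.exceptions import (
    DegenerateInputError,
    SeriesTooShortError,
    ValidationError,
)

from conftest import make_noise_ts


class TestTimeSeriesMatrix:
    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError, match="non-finite"):
            TimeSeriesMatrix(("a",), np.array([[1.0, np.nan, 2.0]]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError, match="unique"):
            TimeSeriesMatrix(("a", "a"), np.zeros((2, 5)))

    def test_rejects_short_series(self):
        with pytest.raises(ValidationError):
            TimeSeriesMatrix(("a",), np.array([[1.0]]))

    def test_rejects_mismatched_ids(self):
        with pytest.raises(ValidationError):
            TimeSeriesMatrix(("a", "b", "c"), np.zeros((2, 5)))


class TestTimeReverse:
    def test_single_row(self):
        ts = TimeSeriesMatrix(("a",), np.array([[1.0, 2.0, 3.0]]))
        assert time_reverse(ts).values.tolist() == [[3.0, 2.0, 1.0]]

    def test_involution(self, noise_ts):
        back = time_reverse(time_reverse(noise_ts))
        np.testing.assert_array_equal(back.values, noise_ts.values)
        assert back.region_ids == noise_ts.region_ids

    def test_palindrome_unchanged(self):
        ts = TimeSeriesMatrix(("a",), np.array([[1.0, 5.0, 1.0]]))
        np.testing.assert_array_equal(time_reverse(ts).values, ts.values)


class TestShiftedPearson:
    def test_identity_shift_zero(self, rng):
        x = rng.normal(size=50)
        assert shifted_pearson(x, x, 0) == pytest.approx(1.0)

    def test_exact_lag_gives_one(self, rng):
        arr = rng.normal(size=51)
        x, y = arr[1:], arr[:-1]  # y(t) = x(t-1)
        assert shifted_pearson(x, y, 1) == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.arange(1.0, 11.0)
        assert shifted_pearson(x, -x, 0) == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            shifted_pearson(np.ones(10), np.arange(10.0), 0)

    def test_zero_variance_policy_zero(self):
        with pytest.warns(UserWarning):
            r = shifted_pearson(np.ones(10), np.arange(10.0), 0, zero_variance="zero")
        assert r == 0.0

    def test_too_short_overlap(self):
        with pytest.raises(SeriesTooShortError):
            shifted_pearson(np.arange(4.0), np.arange(4.0), 2)

    def test_result_in_unit_interval(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            assert -1.0 <= shifted_pearson(x, y, 1) <= 1.0


class TestPairwiseIrreversibility:
    def test_self_is_zero(self, rng):
        x = rng.normal(size=100)
        assert pairwise_irreversibility(x, x, 1) == pytest.approx(0.0, abs=1e-12)

    def test_reversal_invariance(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(size=80)
        a = pairwise_irreversibility(x, y, 1)
        b = pairwise_irreversibility(x[::-1], y[::-1], 1)
        assert a == pytest.approx(b, abs=1e-12)

    def test_var_closed_form(self):
        # y(t) = x(t-1) + eps: c_forward -> 1/sqrt(2), c_reversed -> 0
        g = np.random.default_rng(3)
        n = 100_000
        x = g.normal(size=n + 1)
        y = x[:-1] + g.normal(size=n)
        value = pairwise_irreversibility(x[1:], y, 1)
        assert value == pytest.approx(1 / math.sqrt(2), abs=0.02)


class TestMutualInfoOfCorrelation:
    def test_zero(self):
        assert mutual_info_of_correlation(0.0) == 0.0

    def test_half_log_two(self):
        assert mutual_info_of_correlation(1 / math.sqrt(2)) == pytest.approx(
            math.log(2) / 2, abs=1e-12
        )

    def test_clipped_at_one(self):
        # clip guard: r**2 capped at 1 - 1e-12, so the value is finite
        assert mutual_info_of_correlation(1.0) == pytest.approx(13.8155, abs=1e-3)

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            mutual_info_of_correlation(1.5)

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_even_and_nonnegative(self, r):
        v = mutual_info_of_correlation(r)
        assert v >= 0.0
        assert v == mutual_info_of_correlation(-r)

    def test_strictly_increasing_in_magnitude(self):
        grid = np.linspace(0, 0.999, 50)
        vals = mutual_info_of_correlation(grid)
        assert np.all(np.diff(vals) > 0)


class TestFSMatrix:
    def test_single_region(self, rng):
        x = rng.normal(size=100)
        ts = TimeSeriesMatrix(("a",), x[None, :])
        fs = fs_matrix(ts, 1, "forward")
        expected = mutual_info_of_correlation(shifted_pearson(x, x, 1))
        assert fs.values.shape == (1, 1)
        assert fs.values[0, 0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_reversal_is_transpose(self, seed):
        ts = make_noise_ts(seed, n_regions=5, length=200)
        f = fs_matrix(ts, 1, "forward")
        r = fs_matrix(ts, 1, "reversal")
        np.testing.assert_allclose(r.values, f.values.T, atol=1e-10)

    def test_full_window_transpose_only_approximate(self):
        ts = make_noise_ts(11, n_regions=5, length=200)
        f = fs_matrix(ts, 1, "forward", estimator="full_window")
        r = fs_matrix(ts, 1, "reversal", estimator="full_window")
        # edge terms O(1/L): close but not exact
        assert np.abs(r.values - f.values.T).max() < 0.05

    def test_null_entries_small(self):
        ts = make_noise_ts(42, n_regions=10, length=100_000)
        fs = fs_matrix(ts, 1, "forward")
        off = fs.values[~np.eye(10, dtype=bool)]
        assert np.all(off < 0.005)

    def test_degenerate_region_named(self):
        values = np.vstack([np.ones(50), np.random.default_rng(0).normal(size=50)])
        ts = TimeSeriesMatrix(("flat", "ok"), values)
        with pytest.raises(DegenerateInputError, match="flat"):
            fs_matrix(ts, 1, "forward")


class TestReversibilityMatrix:
    def test_diagonal_zero(self, noise_ts):
        f = fs_matrix(noise_ts, 1, "forward")
        r = fs_matrix(noise_ts, 1, "reversal")
        rev = reversibility_matrix(f, r)
        np.testing.assert_allclose(np.diag(rev.values), 0.0, atol=1e-12)

    def test_equal_inputs_give_zero(self, noise_ts):
        f = fs_matrix(noise_ts, 1, "forward")
        f2 = FSMatrix(f.values, f.shift, "reversal")
        rev = reversibility_matrix(f, f2)
        np.testing.assert_array_equal(rev.values, np.zeros((5, 5)))

    def test_two_by_two_arithmetic(self):
        m = 0.7
        f = FSMatrix(np.array([[0.0, m], [0.0, 0.0]]), 1, "forward")
        r = FSMatrix(np.array([[0.0, 0.0], [m, 0.0]]), 1, "reversal")
        rev = reversibility_matrix(f, r)
        np.testing.assert_allclose(
            rev.values, [[0.0, m**2], [m**2, 0.0]], atol=1e-15
        )

    def test_shape_mismatch(self):
        f = FSMatrix(np.zeros((2, 2)), 1, "forward")
        r = FSMatrix(np.zeros((3, 3)), 1, "reversal")
        with pytest.raises(ValidationError, match="shape"):
            reversibility_matrix(f, r)

    def test_shift_mismatch(self):
        f = FSMatrix(np.zeros((2, 2)), 1, "forward")
        r = FSMatrix(np.zeros((2, 2)), 2, "reversal")
        with pytest.raises(ValidationError, match="shift"):
            reversibility_matrix(f, r)

    def test_symmetric_with_segment_estimator(self):
        ts = make_noise_ts(5, n_regions=6, length=150)
        f = fs_matrix(ts, 1, "forward")
        r = fs_matrix(ts, 1, "reversal")
        rev = reversibility_matrix(f, r)
        np.testing.assert_allclose(rev.values, rev.values.T, atol=1e-10)


class TestGlobalIrreversibility:
    def test_single_region_zero(self, rng):
        ts = TimeSeriesMatrix(("a",), rng.normal(size=(1, 100)))
        assert global_irreversibility(ts, 1) == pytest.approx(0.0, abs=1e-12)

    def test_var_closed_form(self):
        # 2-region unit-weight VAR: I -> mean of [0, m^2, m^2, 0],
        # m = ln(2)/2, i.e. ~0.06006
        g = np.random.default_rng(17)
        n = 100_000
        x = g.normal(size=n + 1)
        y = x[:-1] + g.normal(size=n)
        ts = TimeSeriesMatrix(("x", "y"), np.vstack([x[1:], y]))
        expected = (math.log(2) / 2) ** 2 / 2
        assert global_irreversibility(ts, 1) == pytest.approx(expected, abs=0.005)

    def test_time_reversal_invariance(self, noise_ts):
        a = global_irreversibility(noise_ts, 1)
        b = global_irreversibility(time_reverse(noise_ts), 1)
        assert a == pytest.approx(b, abs=1e-12)

    def test_permutation_invariance(self, directed_pair_ts):
        ts = directed_pair_ts
        flipped = TimeSeriesMatrix(ts.region_ids[::-1], ts.values[::-1])
        assert global_irreversibility(ts, 1) == pytest.approx(
            global_irreversibility(flipped, 1), abs=1e-12
        )

    def test_affine_invariance(self, directed_pair_ts):
        ts = directed_pair_ts
        scaled = TimeSeriesMatrix(
            ts.region_ids, ts.values * np.array([[3.0], [0.25]]) + 7.0
        )
        assert global_irreversibility(ts, 1) == pytest.approx(
            global_irreversibility(scaled, 1), rel=1e-9
        )

    def test_directed_exceeds_noise(self, directed_pair_ts, noise_ts):
        assert global_irreversibility(directed_pair_ts, 1) > global_irreversibility(
            noise_ts, 1
        )

    def test_null_decreases_with_length(self):
        # reversible input: I is pure estimation noise, shrinking with L
        short = [
            global_irreversibility(make_noise_ts(s, 10, 500), 1) for s in range(10)
        ]
        long = [
            global_irreversibility(make_noise_ts(s, 10, 20_000), 1) for s in range(10)
        ]
        assert np.median(long) < np.median(short)
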