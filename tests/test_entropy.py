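"""Unit and property tests for the three entropy estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from feverentropy import (
    UNDEFINED,
    MatchParams,
    SlpEnParams,
    apen_match_diagnostics,
    approximate_entropy,
    is_defined,
    recommended_min_length,
    sample_entropy,
    slope_entropy,
    symbolize_slopes,
)
from feverentropy.entropy import matching_entropy_grid, slope_entropy_grid

from oracles import naive_apen, naive_apen_diagnostics, naive_sampen, naive_slope_entropy

finite_series = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False, width=32),
    min_size=12,
    max_size=60,
)


class TestSymbolizeSlopes:
    def test_zero_differences_map_to_zero_band(self):
        pats = symbolize_slopes([0, 0, 0, 0, 0], SlpEnParams(3, gamma=0.2))
        assert pats.shape == (3, 2)
        assert np.all(pats == 0)

    def test_constant_steep_ramp_single_pattern(self):
        # earlier-minus-later convention: an increasing ramp gives -2 symbols
        pats = symbolize_slopes([0, 1, 2, 3], SlpEnParams(3, gamma=0.5))
        assert pats.shape == (2, 2)
        assert np.all(pats == -2)

    def test_alternating_series_two_patterns(self):
        pats = symbolize_slopes([1, -1, 1, -1, 1, -1, 1], SlpEnParams(3, gamma=0.5))
        as_tuples = [tuple(p) for p in pats]
        assert as_tuples.count((2, -2)) == 3
        assert as_tuples.count((-2, 2)) == 2

    def test_band_boundaries(self):
        # closed zero band, half-open +/-1 bands
        p = SlpEnParams(2, gamma=0.5, delta=0.1)
        x = [0.0, -0.1, -0.6, -0.1, 0.4, 1.0]  # diffs: 0.1, 0.5, -0.5, -0.5, -0.6
        pats = symbolize_slopes(x, p)
        assert [int(v) for v in pats[:, 0]] == [0, 1, -1, -1, -2]

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            symbolize_slopes([1.0, 2.0], SlpEnParams(3, gamma=0.2))

    def test_invalid_thresholds_raise(self):
        with pytest.raises(ValueError):
            SlpEnParams(3, gamma=0.001, delta=0.01)


class TestSlopeEntropy:
    @pytest.mark.parametrize(
        "x",
        [np.zeros(20), np.arange(4.0), np.full(8, 36.6)],
        ids=["constant", "steep-ramp", "constant-37ish"],
    )
    def test_single_pattern_gives_zero(self, x):
        assert slope_entropy(x, SlpEnParams(3, gamma=0.5)) == 0.0

    def test_alternating_series_hand_value(self):
        h = slope_entropy([1, -1, 1, -1, 1, -1, 1], SlpEnParams(3, gamma=0.5))
        expected = -(0.6 * math.log(0.6) + 0.4 * math.log(0.4))
        assert h == pytest.approx(expected, abs=1e-12)

    def test_normalized_variant_in_unit_interval(self, rng):
        x = rng.normal(size=200)
        h = slope_entropy(x, SlpEnParams(4, gamma=0.3), normalize=True)
        assert 0.0 <= h <= 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(finite_series)
    def test_sign_symmetry_exact(self, xs):
        p = SlpEnParams(3, gamma=0.3)
        x = np.asarray(xs)
        assert slope_entropy(x, p) == slope_entropy(-x, p)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(finite_series, st.integers(min_value=-10, max_value=10))
    def test_offset_invariance(self, xs, c):
        p = SlpEnParams(3, gamma=0.3)
        x = np.asarray(xs)
        assert slope_entropy(x + c, p) == pytest.approx(slope_entropy(x, p), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(finite_series, st.integers(min_value=2, max_value=5))
    def test_upper_bound_by_pattern_count(self, xs, m):
        x = np.asarray(xs)
        h = slope_entropy(x, SlpEnParams(m, gamma=0.3))
        assert h <= math.log(min(5 ** (m - 1), x.size - m + 1)) + 1e-12


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.full(30, 5.0), MatchParams(2, 0.2)) == 0.0

    def test_everything_matches_when_r_exceeds_range(self, rng):
        x = rng.uniform(0, 1, size=40)
        assert approximate_entropy(x, MatchParams(2, 2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_linear_series_hand_value(self):
        h = approximate_entropy([1, 2, 3, 4, 5, 6], MatchParams(2, 0.5))
        assert h == pytest.approx(math.log(4 / 5), abs=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            approximate_entropy([1.0, 2.0, 3.0], MatchParams(2, 0.2))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(finite_series, st.integers(min_value=-5, max_value=5))
    def test_offset_invariance(self, xs, c):
        x = np.asarray(xs)
        p = MatchParams(2, 0.4)
        assert approximate_entropy(x + c, p) == pytest.approx(
            approximate_entropy(x, p), abs=1e-12
        )


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(30, 5.0), MatchParams(2, 0.2)) == 0.0

    def test_no_cross_matches_returns_sentinel(self):
        result = sample_entropy([1, 2, 3, 4, 5, 6], MatchParams(2, 0.5))
        assert result is UNDEFINED
        assert not is_defined(result)
        assert not result

    def test_nonnegative_when_defined(self, rng):
        for _ in range(10):
            x = rng.normal(size=80)
            v = sample_entropy(x, MatchParams(2, 0.3))
            if is_defined(v):
                assert v >= 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(finite_series, st.integers(min_value=-5, max_value=5))
    def test_offset_invariance(self, xs, c):
        x = np.asarray(xs)
        p = MatchParams(2, 0.4)
        a, b = sample_entropy(x + c, p), sample_entropy(x, p)
        if is_defined(a) or is_defined(b):
            assert a == pytest.approx(b, abs=1e-12)

    def test_missing_values_rejected(self):
        x = np.arange(20.0)
        x[5] = np.nan
        with pytest.raises(ValueError):
            sample_entropy(x, MatchParams(2, 0.2))


class TestMatchDiagnostics:
    def test_constant_series_full_percentages(self):
        assert apen_match_diagnostics(np.zeros(500), MatchParams(3, 0.2)) == (100.0, 100.0)

    def test_linear_series_only_self_matches(self):
        x = np.arange(1.0, 121.0)
        assert apen_match_diagnostics(x, MatchParams(3, 0.5)) == (0.0, 0.0)

    def test_matches_bruteforce_on_ar1(self, rng):
        x = np.empty(300)
        x[0] = rng.normal()
        for t in range(1, 300):
            x[t] = 0.9 * x[t - 1] + rng.normal(0, math.sqrt(1 - 0.81))
        p = MatchParams(9, 0.2)
        assert apen_match_diagnostics(x, p) == naive_apen_diagnostics(x, 9, 0.2)

    def test_minimum_length_guideline(self):
        assert recommended_min_length(2) == 100
        assert recommended_min_length(3) == 1000


class TestOracleAgreement:
    """Vectorised estimators against the naive references on random data
    (the exhaustive 100-series sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("m,tune", [(2, 0.3), (3, 0.2), (4, 0.6)])
    def test_all_three_match_naive(self, rng, m, tune):
        for _ in range(5):
            x = rng.normal(size=int(rng.integers(25, 90)))
            assert slope_entropy(x, SlpEnParams(max(m, 2), tune)) == pytest.approx(
                naive_slope_entropy(x, max(m, 2), tune), abs=1e-12
            )
            assert approximate_entropy(x, MatchParams(m, tune)) == pytest.approx(
                naive_apen(x, m, tune), abs=1e-12
            )
            got = sample_entropy(x, MatchParams(m, tune))
            ref = naive_sampen(x, m, tune)
            if ref is None:
                assert got is UNDEFINED
            else:
                assert got == pytest.approx(ref, abs=1e-12)


class TestGridHelpers:
    def test_slope_grid_matches_single_calls(self, rng):
        x = rng.normal(size=120)
        ms, gs = [3, 5], [0.15, 0.4]
        grid = slope_entropy_grid(x, ms, gs)
        for i, m in enumerate(ms):
            for j, g in enumerate(gs):
                assert grid[i, j] == pytest.approx(
                    slope_entropy(x, SlpEnParams(m, g)), abs=1e-12
                )

    def test_matching_grid_matches_single_calls(self, rng):
        x = rng.normal(size=100)
        ms, rs = [2, 4], [0.2, 0.7]
        apen, sampen = matching_entropy_grid(x, ms, rs)
        for i, m in enumerate(ms):
            for j, r in enumerate(rs):
                assert apen[i, j] == pytest.approx(
                    approximate_entropy(x, MatchParams(m, r)), abs=1e-12
                )
                single = sample_entropy(x, MatchParams(m, r))
                if is_defined(single):
                    assert sampen[i, j] == pytest.approx(single, abs=1e-12)
                else:
                    assert np.isnan(sampen[i, j])
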