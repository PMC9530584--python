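"""Detrended fluctuation function: hand oracles, brute force, invariances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dffglu.dff import (
    FluctuationProfiler,
    _window_rss,
    fluctuation,
    fluctuation_profile,
    integrate_series,
)
from dffglu.exceptions import InputError, ScaleError
from dffglu.io import GlucoseTrace

series_arrays = arrays(
    np.float64, st.integers(8, 120),
    elements=st.floats(-50, 50, allow_nan=False, width=64))


def brute_force_fd(x, l):
    """Independent loop-based reference: integrate, window, polyfit, RMS."""
    x = np.asarray(x, dtype=float)
    mean = sum(x) / len(x)
    y = []
    acc = 0.0
    for v in x:
        acc += v - mean
        y.append(acc)
    m = len(y) // l
    sq = []
    for w in range(m):
        win = y[w * l:(w + 1) * l]
        t = list(range(l))
        coef = np.polyfit(t, win, 1)
        for ti, yi in zip(t, win):
            sq.append((yi - (coef[0] * ti + coef[1])) ** 2)
    return (sum(sq) / (m * l)) ** 0.5


class TestIntegrate:
    def test_two_point_hand_case(self):
        np.testing.assert_allclose(integrate_series([1.0, 3.0]), [-1.0, 0.0])

    def test_constant_is_zero(self):
        np.testing.assert_allclose(integrate_series([4.2] * 6), np.zeros(6), atol=1e-12)

    @given(series_arrays)
    def test_final_element_conserved(self, x):
        assert integrate_series(x)[-1] == pytest.approx(0.0, abs=1e-7 * (1 + np.abs(x).max()))

    def test_too_short_errors(self):
        with pytest.raises(InputError):
            integrate_series([1.0])


class TestFluctuation:
    def test_constant_input_zero(self):
        assert fluctuation([5.0] * 12, 4) == pytest.approx(0.0, abs=1e-12)

    def test_worked_square_wave(self):
        # x=[1,3,...]: y=[-1,0,-1,0,...], two windows of 4, RMS residual sqrt(0.2)
        assert fluctuation([1, 3, 1, 3, 1, 3, 1, 3], 4) == pytest.approx(
            np.sqrt(0.2), abs=1e-12)

    def test_scale_errors(self):
        with pytest.raises(ScaleError):
            fluctuation([1.0, 2.0, 3.0], 1)
        with pytest.raises(ScaleError):
            fluctuation([1.0, 2.0, 3.0], 4)

    @given(series_arrays, st.floats(-4, 4), st.floats(-10, 10), st.integers(2, 8))
    def test_homogeneity(self, x, a, b, l):
        f0 = fluctuation(x, l)
        f1 = fluctuation(a * x + b, l)
        assert f1 == pytest.approx(abs(a) * f0, rel=1e-9, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 300))
            l = int(rng.integers(2, max(3, n // 2)))
            x = rng.normal(8, 3, n)
            got = fluctuation(x, l)
            want = brute_force_fd(x, l)
            assert got == pytest.approx(want, rel=1e-10)

    def test_retained_points_follow_windowing_rule(self, rng):
        # the documented remainder rule: floor(N/l)*l points enter the RMS
        for n, l in [(100, 7), (50, 50), (23, 5)]:
            y = np.cumsum(rng.normal(size=n))
            _, k = _window_rss(y, l)
            assert k == (n // l) * l


class TestProfile:
    def test_full_range_on_week_trace(self, rng):
        x = rng.normal(8, 2, 2016)
        prof = fluctuation_profile(x, 2, 130)
        assert len(prof) == 129
        assert np.all(np.isfinite(prof.f_values))
        assert np.all(prof.f_values >= 0)

    def test_consistent_with_single_scale_calls(self, rng):
        x = rng.normal(8, 2, 500)
        prof = fluctuation_profile(x, 2, 60)
        for l in (2, 17, 60):
            assert prof[l] == pytest.approx(fluctuation(x, l), rel=1e-12)

    def test_gap_split_windows_do_not_cross(self, rng):
        vals = rng.uniform(4, 12, 60)
        # two 30-sample segments separated by a 2-hour hole
        time_s = np.concatenate([np.arange(30), np.arange(54, 84)]) * 300
        trace = GlucoseTrace("p", time_s, vals)
        assert len(trace.segments()) == 2
        prof = fluctuation_profile(trace, 2, 40)
        # manual pooled computation with the shared global mean
        y = np.cumsum(vals - vals.mean())
        for l in (7, 30):
            rss = k = 0
            for seg in (y[:30], y[30:]):
                r, n = _window_rss(seg, l)
                rss, k = rss + r, k + n
            assert prof[l] == pytest.approx(np.sqrt(rss / k), rel=1e-12)
        # scales longer than the longest segment are unusable
        assert np.isnan(prof.f_values[prof.scales > 30]).all()

    def test_too_short_trace_reports_usable_scales(self):
        with pytest.raises(InputError, match="2..4"):
            fluctuation_profile(np.arange(4.0) + 5, 5, 10)

    def test_profiler_transform_shape_and_params(self, rng):
        traces = [rng.normal(8, 2, 300) for _ in range(4)]
        prof = FluctuationProfiler(l_min=2, l_max=50)
        F = prof.fit_transform(traces)
        assert F.shape == (4, 49)
        assert prof.get_params() == {"l_min": 2, "l_max": 50}
        assert np.all(F >= 0)


class TestScalingLaws:
    """DFA theory: slope ~0.5 for white noise, ~1.5 for its running sum."""

    @staticmethod
    def _slope(x):
        prof = fluctuation_profile(x, 10, 100)
        return np.polyfit(np.log(prof.scales), np.log(prof.f_values), 1)[0]

    def test_white_noise_slope(self):
        x = np.random.default_rng(42).standard_normal(5040)
        assert self._slope(x) == pytest.approx(0.5, abs=0.08)

    def test_random_walk_slope(self):
        x = np.cumsum(np.random.default_rng(42).standard_normal(5040))
        assert self._slope(x) == pytest.approx(1.5, abs=0.12)
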