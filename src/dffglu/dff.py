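"""Detrended fluctuation function F_d(l) for CGM glucose series.

The statistic is the raw fluctuation value of first-order detrended
fluctuation analysis at a fixed window length l (in samples), used directly
as a per-patient score rather than being reduced to a scaling exponent:

1. integrate the mean-centred glucose series,
   y(t) = sum_{i<=t} (x(i) - mean(x));
2. partition y into m = floor(N / l) consecutive non-overlapping windows of
   length l from the start, discarding the trailing remainder;
3. remove the ordinary-least-squares line from each window;
4. F_d(l) = sqrt( (1 / (m*l)) * sum of squared residuals over all retained
   points ).

Windows are forward-only with no reverse pass and no overlap, and detrending
is strictly linear. Multi-day recordings are treated as one contiguous
sequence: the mean is taken over the full recording. When a trace was split
at long sensor gaps, each segment is windowed separately (windows never span
a gap) and the squared residuals are pooled before the root mean square.

At the nominal 5-minute CGM cadence a window of l=100 samples spans
(100-1) * 5 min = 8 h 15 min first-to-last, and a full day holds 288 samples.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InputError, ScaleError
from .io import GlucoseTrace

__all__ = [
    "integrate_series",
    "fluctuation",
    "fluctuation_profile",
    "profile_matrix",
    "window_span_hours",
    "samples_per_day",
    "FluctuationProfile",
    "FluctuationProfiler",
]


def window_span_hours(l: int, sampling_interval: int = 300) -> float:
    """Duration in hours spanned first-to-last by a window of ``l`` samples."""
    return (l - 1) * sampling_interval / 3600.0


def samples_per_day(sampling_interval: int = 300) -> int:
    """Number of samples in 24 h at the given cadence (288 at 5 min)."""
    return 86400 // sampling_interval


def integrate_series(values) -> np.ndarray:
    """Cumulative deviation from the mean; the final element is ~0."""
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise InputError("integrate_series needs a 1-D sequence of length >= 2")
    if not np.all(np.isfinite(x)):
        raise InputError("integrate_series: values must be finite")
    return np.cumsum(x - x.mean())


def _window_rss(y: np.ndarray, l: int) -> tuple[float, int]:
    """Pooled squared residual of per-window OLS detrending.

    Returns (sum of squared residuals, number of retained points m*l);
    (0.0, 0) when the segment holds no full window.
    """
    m = y.size // l
    if m == 0:
        return 0.0, 0
    Y = y[: m * l].reshape(m, l)
    t = np.arange(l, dtype=np.float64)
    tc = t - t.mean()
    denom = float(tc @ tc)
    slope = (Y @ tc) / denom
    resid = Y - Y.mean(axis=1, keepdims=True) - slope[:, None] * tc
    return float(np.einsum("ij,ij->", resid, resid)), m * l


def fluctuation(values, l: int) -> float:
    """F_d(l) of a single contiguous glucose sequence."""
    if not isinstance(l, numbers.Integral):
        raise ScaleError(f"window length must be an integer, got {l!r}")
    l = int(l)
    if l < 2:
        raise ScaleError(f"window length must be >= 2, got {l}")
    x = np.asarray(values, dtype=np.float64)
    if l > x.size:
        raise ScaleError(f"window length {l} exceeds series length {x.size}")
    y = integrate_series(x)
    rss, k = _window_rss(y, l)
    return float(np.sqrt(rss / k))


class FluctuationProfile:
    """Map l -> F_d(l) for one patient over a range of scales."""

    def __init__(self, patient_id: str, scales, f_values):
        self.patient_id = patient_id
        self.scales = np.asarray(scales, dtype=np.int64)
        self.f_values = np.asarray(f_values, dtype=np.float64)
        if self.scales.shape != self.f_values.shape:
            raise InputError("scales and f_values must have equal length")
        if np.any(np.diff(self.scales) <= 0):
            raise InputError("scales must be strictly increasing")
        finite = self.f_values[np.isfinite(self.f_values)]
        if np.any(finite < 0):
            raise InputError("fluctuation values must be non-negative")

    def __getitem__(self, l: int) -> float:
        idx = np.searchsorted(self.scales, l)
        if idx >= len(self.scales) or self.scales[idx] != l:
            raise KeyError(f"scale {l} not in profile")
        return float(self.f_values[idx])

    def __len__(self) -> int:
        return len(self.scales)


def _trace_segments(trace) -> list[np.ndarray]:
    if isinstance(trace, GlucoseTrace):
        vals = trace.values
        return [vals[s] for s in trace.segments()]
    return [np.asarray(trace, dtype=np.float64)]


def fluctuation_profile(trace, l_min: int = 2, l_max: int = 130) -> FluctuationProfile:
    """F_d(l) for every integer l in [l_min, l_max].

    For traces split at long gaps the integration runs over the full
    mean-centred recording (one global mean), while windows are confined to
    contiguous segments and residual sums pooled across them. Scales longer
    than the longest segment are reported as NaN; if no requested scale is
    usable an :class:`InputError` lists the usable range.
    """
    if l_min < 2:
        raise ScaleError(f"l_min must be >= 2, got {l_min}")
    if l_max < l_min:
        raise ScaleError(f"l_max ({l_max}) < l_min ({l_min})")
    segments = _trace_segments(trace)
    values = np.concatenate(segments)
    if values.size < 2:
        raise InputError("trace too short for any fluctuation computation")
    y = np.cumsum(values - values.mean())
    seg_lens = [s.size for s in segments]
    longest = max(seg_lens)
    if longest < l_min:
        raise InputError(
            f"trace supports no requested scale: usable scales are 2..{longest}, "
            f"requested {l_min}..{l_max}")
    bounds = np.concatenate(([0], np.cumsum(seg_lens)))
    y_segs = [y[a:b] for a, b in zip(bounds[:-1], bounds[1:])]

    scales = np.arange(l_min, l_max + 1)
    f = np.full(scales.shape, np.nan)
    for i, l in enumerate(scales):
        if l > longest:
            break
        rss = 0.0
        k = 0
        for ys in y_segs:
            r, n = _window_rss(ys, int(l))
            rss += r
            k += n
        if k:
            f[i] = np.sqrt(rss / k)
    pid = trace.patient_id if isinstance(trace, GlucoseTrace) else ""
    return FluctuationProfile(pid, scales, f)


def profile_matrix(traces, l_min: int = 2, l_max: int = 130) -> np.ndarray:
    """Stack per-patient profiles into an (n_patients, n_scales) array."""
    return FluctuationProfiler(l_min=l_min, l_max=l_max).fit_transform(traces)


class FluctuationProfiler(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer turning glucose traces into F_d(l) features.

    Parameters
    ----------
    l_min, l_max : int
        Inclusive range of window lengths (in samples); defaults cover the
        clinically explored band 2..130 at 5-minute sampling.

    ``transform`` accepts a list of :class:`~dffglu.io.GlucoseTrace` or 1-D
    numeric sequences (each one patient) and returns an
    ``(n_patients, l_max - l_min + 1)`` array; entries for scales a short
    trace cannot support are NaN.
    """

    def __init__(self, l_min: int = 2, l_max: int = 130):
        self.l_min = l_min
        self.l_max = l_max

    def fit(self, X, y=None):
        if self.l_min < 2 or self.l_max < self.l_min:
            raise ScaleError(
                f"invalid scale range [{self.l_min}, {self.l_max}]")
        self.scales_ = np.arange(self.l_min, self.l_max + 1)
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "scales_"):
            self.fit(X)
        rows = [fluctuation_profile(t, self.l_min, self.l_max).f_values for t in X]
        return np.vstack(rows) if rows else np.empty((0, len(self.scales_)))

    def profiles(self, traces) -> list[FluctuationProfile]:
        """Per-patient :class:`FluctuationProfile` objects (keeps ids)."""
        return [fluctuation_profile(t, self.l_min, self.l_max) for t in traces]
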