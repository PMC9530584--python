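"""Classical CGM summary metrics: mean glucose, SD, %CV, TIR and MAGE.

Conventions (stated because published variants disagree):

* SD uses the sample (N-1) denominator throughout.
* %CV = 100 * SD / mean.
* TIR counts samples with 3.9 <= g <= 10.0 mmol/L, bounds inclusive, each
  sample weighted equally (ingest regularizes traces onto a uniform grid, so
  sample weighting and time weighting coincide).
* MAGE reduces the trace to alternating turning points (monotone runs and
  plateaus merged), takes absolute differences between consecutive turning
  points, keeps excursions exceeding one whole-trace SD, and averages them —
  both ascending and descending excursions count (the "MAGE-avg" variant).
  Returns 0 when no excursion qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InputError
from .io import GlucoseTrace

__all__ = [
    "TIR_RANGE",
    "MetricSet",
    "time_in_range",
    "cv_percent",
    "mage",
    "summarize_trace",
    "GlycemicMetricsExtractor",
]

#: normoglycemic target range, mmol/L (inclusive on both ends)
TIR_RANGE = (3.9, 10.0)

METRIC_NAMES = ("mean_glucose", "sd", "cv_percent", "tir_percent", "mage")


@dataclass(frozen=True)
class MetricSet:
    mean_glucose: float
    sd: float
    cv_percent: float
    tir_percent: float
    mage: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in METRIC_NAMES])


def _values(trace) -> np.ndarray:
    if isinstance(trace, GlucoseTrace):
        return trace.values
    x = np.asarray(trace, dtype=np.float64)
    if x.ndim != 1:
        raise InputError("expected a 1-D glucose sequence")
    if x.size and not np.all(np.isfinite(x)):
        raise InputError("glucose values must be finite")
    return x


def time_in_range(trace, low: float = TIR_RANGE[0], high: float = TIR_RANGE[1]) -> float:
    """Percent of samples with low <= g <= high (inclusive bounds)."""
    x = _values(trace)
    if x.size == 0:
        raise InputError("time_in_range: empty trace")
    return 100.0 * float(np.mean((x >= low) & (x <= high)))


def cv_percent(trace) -> float:
    """Coefficient of variation, 100 * SD / mean, SD with N-1 denominator."""
    x = _values(trace)
    if x.size < 2:
        raise InputError("cv_percent: need at least 2 samples")
    mean = float(x.mean())
    if mean <= 0:
        raise InputError("cv_percent: mean glucose must be positive")
    return 100.0 * float(x.std(ddof=1)) / mean


def _turning_points(x: np.ndarray) -> np.ndarray:
    """Alternating local extrema, endpoints included, plateaus merged."""
    keep = np.concatenate(([True], np.diff(x) != 0))
    x = x[keep]  # merge plateaus
    if x.size < 3:
        return x
    d = np.sign(np.diff(x))
    turn = np.concatenate(([True], d[1:] != d[:-1], [True]))
    return x[turn]


def mage(trace) -> float:
    """Mean amplitude of glycemic excursions (both directions counted)."""
    x = _values(trace)
    if x.size < 3:
        raise InputError("mage: need at least 3 samples")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return 0.0
    tp = _turning_points(x)
    if tp.size < 2:
        return 0.0
    exc = np.abs(np.diff(tp))
    qual = exc[exc > sd]
    return float(qual.mean()) if qual.size else 0.0


def summarize_trace(trace) -> MetricSet:
    """All five classical metrics for one trace, mutually consistent."""
    x = _values(trace)
    if x.size < 3:
        raise InputError("summarize_trace: need at least 3 samples")
    sd = float(x.std(ddof=1))
    return MetricSet(
        mean_glucose=float(x.mean()),
        sd=sd,
        cv_percent=cv_percent(x),
        tir_percent=time_in_range(x),
        mage=mage(x),
    )


class GlycemicMetricsExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping traces to the five classical metric columns.

    Output column order: mean_glucose, sd, cv_percent, tir_percent, mage
    (also exposed as ``feature_names_out_``).
    """

    def fit(self, X, y=None):
        self.feature_names_out_ = list(METRIC_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit(X)
        return np.vstack([summarize_trace(t).as_array() for t in X]) if len(X) \
            else np.empty((0, len(METRIC_NAMES)))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(METRIC_NAMES, dtype=object)
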