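"""Data-driven selection of the detrending scale l*.

For every window length l the fluctuation values F_d(l) across the cohort
are rank-correlated (Spearman, average ranks for ties) with fasting
C-peptide and with 2-hour postprandial C-peptide. The working scale l* is
the one maximizing |r| against *fasting* C-peptide; the postprandial curve
is reported alongside but not optimized. Ties break toward the smallest l.

Because the criterion is rank-based, the selected scale is invariant to any
strictly monotone transform of the C-peptide values. No multiplicity
correction is applied across scales: this is a selection procedure, not a
family of hypothesis tests, and is reported as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InputError, UndefinedStatisticError

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "spearman_curve",
    "correlation_curve",
    "select_optimal_scale",
    "ScaleSelectionResult",
    "ScaleSelector",
]


def spearman(a, b) -> float:
    """Spearman rank correlation with average ranks for ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise InputError("spearman needs at least 3 paired observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InputError("spearman: inputs must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("spearman undefined for zero-variance input")
    return float(stats.spearmanr(a, b).statistic)


def spearman_curve(F: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Spearman of each column of F against v, vectorized via rank-Pearson.

    Columns with zero rank variance yield NaN rather than raising, since a
    whole curve should not die on one degenerate scale.
    """
    F = np.asarray(F, dtype=float)
    v = np.asarray(v, dtype=float)
    rv = stats.rankdata(v)
    rv = rv - rv.mean()
    sv = np.sqrt(rv @ rv)
    RF = stats.rankdata(F, axis=0)
    RF = RF - RF.mean(axis=0)
    sF = np.sqrt(np.einsum("ij,ij->j", RF, RF))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rv @ RF) / (sv * sF)
    return r


@dataclass
class ScaleSelectionResult:
    """Per-scale correlation curves and (once selected) the working scale."""

    scales: list[int]
    r_fcp: list[float]
    r_c2h: list[float]
    n_used: list[int]
    l_star: int | None = None
    r_star: float | None = None
    dropped_scales: list[int] = field(default_factory=list)

    def __post_init__(self):
        for curve in (self.r_fcp, self.r_c2h):
            arr = np.asarray(curve, dtype=float)
            if np.any(np.abs(arr[np.isfinite(arr)]) > 1 + 1e-12):
                raise InputError("correlation coefficients must lie in [-1, 1]")


def correlation_curve(profiles, cohort, scales=None) -> ScaleSelectionResult:
    """Spearman curves r_fcp(l), r_c2h(l) across a cohort.

    ``profiles`` is either a list of :class:`~dffglu.dff.FluctuationProfile`
    aligned with ``cohort`` records (matched by patient_id) or an
    (n_patients, n_scales) matrix. Patients lacking a given scale (NaN) are
    dropped pairwise at that scale; scales with fewer than 3 usable patients
    are dropped entirely (recorded in ``dropped_scales``).
    """
    if hasattr(profiles, "ndim"):
        F = np.asarray(profiles, dtype=float)
        if scales is None:
            scales = np.arange(2, 2 + F.shape[1])
        else:
            scales = np.asarray(scales, dtype=int)
            if scales.shape[0] != F.shape[1]:
                raise InputError("scales length must match profile matrix columns")
    else:
        by_id = {p.patient_id: p for p in profiles}
        missing = [pid for pid in cohort.patient_ids if pid not in by_id]
        if missing:
            raise InputError(f"profiles missing for patients: {missing}")
        scales = by_id[cohort.patient_ids[0]].scales
        F = np.vstack([by_id[pid].f_values for pid in cohort.patient_ids])
    if F.shape[0] != len(cohort):
        raise InputError("profile matrix row count does not match cohort size")
    if F.shape[0] == 0 or F.shape[1] == 0:
        raise InputError("empty profile matrix")

    fcp, c2h = cohort.fcp, cohort.c2h
    out_scales, r_f, r_c, n_used, dropped = [], [], [], [], []
    full = np.all(np.isfinite(F))
    if full:
        r_f_all = spearman_curve(F, fcp)
        r_c_all = spearman_curve(F, c2h)
    for j, l in enumerate(scales):
        ok = np.isfinite(F[:, j])
        n = int(ok.sum())
        if n < 3:
            dropped.append(int(l))
            logger.warning("scale %d dropped: only %d usable patients", l, n)
            continue
        if full:
            rf, rc = float(r_f_all[j]), float(r_c_all[j])
        else:
            if n < len(cohort):
                logger.info("scale %d: %d patients dropped pairwise",
                            l, len(cohort) - n)
            rf = float(spearman_curve(F[ok, j:j + 1], fcp[ok])[0])
            rc = float(spearman_curve(F[ok, j:j + 1], c2h[ok])[0])
        out_scales.append(int(l))
        r_f.append(rf)
        r_c.append(rc)
        n_used.append(n)
    if not out_scales:
        raise InputError("no scale has at least 3 usable patients")
    return ScaleSelectionResult(out_scales, r_f, r_c, n_used, dropped_scales=dropped)


def select_optimal_scale(result: ScaleSelectionResult) -> ScaleSelectionResult:
    """Fill l_star / r_star: argmax of |r_fcp|, ties toward the smallest l."""
    if not result.scales:
        raise InputError("empty correlation curve")
    r = np.asarray(result.r_fcp, dtype=float)
    absr = np.where(np.isfinite(r), np.abs(r), -np.inf)
    if not np.any(np.isfinite(r)):
        raise InputError("all correlation coefficients undefined")
    idx = int(np.argmax(absr))  # first occurrence == smallest l (scales ascending)
    result.l_star = int(result.scales[idx])
    result.r_star = float(r[idx])
    return result


class ScaleSelector(TransformerMixin, BaseEstimator):
    """Scikit-learn selector of the single most C-peptide-informative scale.

    ``fit(X, y)`` takes the fluctuation matrix X (n_patients, n_scales) and
    the fasting C-peptide vector y; ``transform(X)`` returns the selected
    column as an (n, 1) score matrix.

    Parameters
    ----------
    scales : array-like of int or None
        Window length labelling the columns of X; defaults to 2, 3, ...
    """

    def __init__(self, scales=None):
        self.scales = scales

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InputError("X must be (n_patients, n_scales) aligned with y")
        scales = (np.arange(2, 2 + X.shape[1]) if self.scales is None
                  else np.asarray(self.scales, dtype=int))
        if scales.shape[0] != X.shape[1]:
            raise InputError("scales length must match number of columns in X")
        r = spearman_curve(X, y)
        absr = np.where(np.isfinite(r), np.abs(r), -np.inf)
        idx = int(np.argmax(absr))
        self.scales_ = scales
        self.curve_ = r
        self.selected_index_ = idx
        self.l_star_ = int(scales[idx])
        self.r_star_ = float(r[idx])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_index_:self.selected_index_ + 1]
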