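"""Evaluating per-patient scores as LADA-vs-T2DM classifiers.

Any scalar marker (F_d(l*), TIR, mean glucose, SD, MAGE, %CV) is assessed
by ROC analysis: the marker is first oriented so that the class-median order
puts the positive class (LADA by default) on the high side, AUC is computed
on the oriented scores (ties count 1/2), a 95% CI comes from the DeLong
variance estimator, and a single operating point is chosen by maximizing
Youden's J = sensitivity + specificity - 1 over midpoints between adjacent
distinct scores (J ties break toward higher specificity). Agreement between
the thresholded marker and the clinical diagnosis is summarized by Cohen's
kappa.

Stability is probed by stratified 10-fold cross-validation in which both
tunable quantities — the scale l* and the cutoff — are re-derived on each
training set and applied frozen to the held-out fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dff import profile_matrix
from .exceptions import InputError, UndefinedStatisticError
from .metrics import GlycemicMetricsExtractor
from .selection import ScaleSelector, spearman

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "CVFold",
    "ClassificationReport",
    "roc_analysis",
    "youden_cutoff",
    "cohen_kappa",
    "ten_fold_cv",
    "compare_markers",
    "YoudenThresholdClassifier",
    "DffScaleClassifier",
]


# --------------------------------------------------------------------------
# report containers (JSON-native field types so reports round-trip exactly)

@dataclass
class ROCResult:
    marker_name: str
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float          # percent
    specificity: float          # percent
    orientation: str            # 'higher' or 'lower' score indicates positive

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise InputError(f"AUC out of [0, 1]: {self.auc}")
        if not (self.auc_ci_low - 1e-12 <= self.auc <= self.auc_ci_high + 1e-12):
            raise InputError("AUC must lie inside its confidence interval")


@dataclass
class CVFold:
    fold_index: int
    l_selected: int
    train_auc: float
    train_sensitivity: float
    train_specificity: float
    test_auc: float | None
    test_sensitivity: float | None
    test_specificity: float | None
    test_index: list[int] = field(default_factory=list)  # held-out row indices


@dataclass
class ClassificationReport:
    markers: list[ROCResult] = field(default_factory=list)
    correlations: dict = field(default_factory=dict)
    kappa: float | None = None
    l_star: int | None = None
    r_star: float | None = None
    cv_folds: list[CVFold] = field(default_factory=list)
    cv_means: dict = field(default_factory=dict)
    cv_ci: dict = field(default_factory=dict)
    seed: int | None = None
    config: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# core statistics

def _check_two_class(scores, labels, positive_class):
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if s.shape != lab.shape or s.ndim != 1:
        raise InputError("scores and labels must be equal-length 1-D sequences")
    if not np.all(np.isfinite(s)):
        raise InputError("scores must be finite")
    y = lab == positive_class
    if y.sum() == 0 or (~y).sum() == 0:
        raise InputError("both classes must be present")
    return s, y


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(z)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance for oriented scores (higher = positive)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n            # structural components per positive
    v10 = 1.0 - (tz[m:] - ty) / m      # per negative
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def youden_cutoff(scores, labels, positive_class: str = "LADA"
                  ) -> tuple[float, float, float]:
    """(cutoff, sensitivity %, specificity %) maximizing Youden's J.

    Assumes higher scores indicate the positive class (orient beforehand if
    needed); candidate cutoffs are midpoints between adjacent distinct score
    values, the rule being "predict positive when score >= cutoff". J ties
    break toward higher specificity (then toward the higher cutoff).
    """
    s, y = _check_two_class(scores, labels, positive_class)
    distinct = np.unique(s)
    if distinct.size == 1:
        return float(distinct[0]), 100.0, 0.0
    cands = (distinct[:-1] + distinct[1:]) / 2.0
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    sens = 1.0 - np.searchsorted(pos, cands, side="left") / len(pos)
    spec = np.searchsorted(neg, cands, side="left") / len(neg)
    j = sens + spec - 1.0
    tie = j >= j.max() - 1e-12
    best_spec = spec[tie].max()
    idx = int(np.flatnonzero(tie & (spec >= best_spec - 1e-12))[-1])
    return float(cands[idx]), 100.0 * float(sens[idx]), 100.0 * float(spec[idx])


def _orient(scores, y) -> tuple[np.ndarray, str]:
    """Orient so the positive class sits high: flip when the rank AUC is
    below 1/2; an exact 1/2 is broken by class-median order."""
    auc, _ = delong_auc_variance(scores[y], scores[~y])
    if auc == 0.5:
        higher = np.median(scores[y]) >= np.median(scores[~y])
    else:
        higher = auc > 0.5
    return (scores, "higher") if higher else (-scores, "lower")


def roc_analysis(scores, labels, positive_class: str = "LADA",
                 marker_name: str = "", ci_level: float = 0.95) -> ROCResult:
    """Full ROC summary of one marker (orientation, AUC + DeLong CI, cutoff)."""
    s, y = _check_two_class(scores, labels, positive_class)
    if y.sum() < 2 or (~y).sum() < 2:
        raise InputError("need at least 2 patients per class for ROC analysis")
    oriented, orientation = _orient(s, y)
    auc = float(roc_auc_score(y, oriented))
    _, var = delong_auc_variance(oriented[y], oriented[~y])
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(var)
    cut_or, sens, spec = youden_cutoff(oriented, labels, positive_class)
    return ROCResult(
        marker_name=marker_name,
        auc=auc,
        auc_ci_low=float(max(0.0, auc - half)),
        auc_ci_high=float(min(1.0, auc + half)),
        cutoff=float(cut_or if orientation == "higher" else -cut_or),
        sensitivity=sens,
        specificity=spec,
        orientation=orientation,
    )


def cohen_kappa(predicted, actual) -> float:
    """Chance-corrected agreement between predicted and actual class labels."""
    p = np.asarray(predicted)
    a = np.asarray(actual)
    if p.shape != a.shape or p.ndim != 1 or p.size == 0:
        raise InputError("predicted and actual must be equal-length 1-D sequences")
    labels = np.unique(np.concatenate([p, a]))
    po = float(np.mean(p == a))
    pe = float(sum(np.mean(p == lab) * np.mean(a == lab) for lab in labels))
    if pe >= 1.0:
        raise UndefinedStatisticError(
            "kappa undefined: chance agreement is 1 (both label sequences constant)")
    return (po - pe) / (1.0 - pe)


# --------------------------------------------------------------------------
# estimators

class YoudenThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-score threshold classifier with auto-orientation.

    ``fit`` orients the score by class medians (so the positive class sits on
    the high side of the oriented score), then places the cutoff at the
    Youden-optimal midpoint. ``decision_function`` returns oriented score
    minus cutoff; ``predict`` assigns the positive class where it is >= 0.
    """

    def __init__(self, positive_label: str | None = None):
        self.positive_label = positive_label

    def _scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise InputError("expected a single score column")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        s = self._scores(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise InputError(f"need exactly 2 classes, got {list(self.classes_)}")
        pos = self.positive_label if self.positive_label is not None else self.classes_[-1]
        if pos not in self.classes_:
            raise InputError(f"positive_label {pos!r} not among classes")
        mask = y == pos
        oriented, self.orientation_ = _orient(s, mask)
        self.cutoff_, self.sensitivity_, self.specificity_ = youden_cutoff(
            oriented, y, pos)
        self.positive_label_ = pos
        self.negative_label_ = self.classes_[self.classes_ != pos][0]
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        s = self._scores(X)
        oriented = s if self.orientation_ == "higher" else -s
        return oriented - self.cutoff_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d >= 0, self.positive_label_, self.negative_label_)

    @property
    def cutoff_original_units_(self) -> float:
        """Cutoff on the raw marker scale (sign restored for 'lower')."""
        return self.cutoff_ if self.orientation_ == "higher" else -self.cutoff_


class DffScaleClassifier(ClassifierMixin, BaseEstimator):
    """Fluctuation-scale classifier: pick l* by |Spearman| with fasting
    C-peptide on the training set, then threshold F_d(l*) at the
    Youden-optimal cutoff.

    ``fit(X, y, fcp=...)`` takes the fluctuation matrix (n_patients,
    n_scales) and diagnosis labels, plus the training patients' fasting
    C-peptide as a fit parameter (it is a selection covariate, not a
    feature).
    """

    def __init__(self, scales=None, positive_label: str = "LADA"):
        self.scales = scales
        self.positive_label = positive_label

    def fit(self, X, y, fcp=None):
        if fcp is None:
            raise InputError("DffScaleClassifier.fit requires fcp=<training FCP>")
        self.selector_ = ScaleSelector(scales=self.scales).fit(X, fcp)
        scores = self.selector_.transform(X)
        self.threshold_ = YoudenThresholdClassifier(
            positive_label=self.positive_label).fit(scores, y)
        self.classes_ = self.threshold_.classes_
        self.l_star_ = self.selector_.l_star_
        self.r_star_ = self.selector_.r_star_
        self.orientation_ = self.threshold_.orientation_
        self.cutoff_ = self.threshold_.cutoff_original_units_
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        return self.threshold_.decision_function(self.selector_.transform(X))

    def predict(self, X) -> np.ndarray:
        return self.threshold_.predict(self.selector_.transform(X))


# --------------------------------------------------------------------------
# cross-validation protocol and marker comparison

def _sens_spec(pred, y_true_mask, positive_label) -> tuple[float | None, float | None]:
    pred_pos = np.asarray(pred) == positive_label
    npos = int(y_true_mask.sum())
    nneg = int((~y_true_mask).sum())
    sens = 100.0 * float(pred_pos[y_true_mask].mean()) if npos else None
    spec = 100.0 * float((~pred_pos[~y_true_mask]).mean()) if nneg else None
    return sens, spec


def ten_fold_cv(cohort, F=None, l_min: int = 2, l_max: int = 130,
                seed: int = 0, n_folds: int = 10,
                positive_class: str = "LADA"):
    """Stratified k-fold protocol with per-fold re-selection of l* and cutoff.

    Returns (folds, means, ci, warnings): per-fold :class:`CVFold` rows, the
    arithmetic means across folds, t-based 95% CIs of those means, and any
    warnings (e.g. single-class test folds, whose test metrics are missing).
    """
    labels = cohort.labels
    fcp = cohort.fcp
    if F is None:
        F = profile_matrix(cohort.traces, l_min, l_max)
    F = np.asarray(F, dtype=float)
    scales = np.arange(l_min, l_max + 1)
    if F.shape != (len(cohort), len(scales)):
        raise InputError("fluctuation matrix shape does not match cohort/scales")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds: list[CVFold] = []
    warnings: list[str] = []
    for k, (tr, te) in enumerate(skf.split(F, labels), start=1):
        clf = DffScaleClassifier(scales=scales, positive_label=positive_class)
        clf.fit(F[tr], labels[tr], fcp=fcp[tr])

        ytr = labels[tr] == positive_class
        dtr = clf.decision_function(F[tr])
        train_auc = float(roc_auc_score(ytr, dtr))
        train_sens = clf.threshold_.sensitivity_
        train_spec = clf.threshold_.specificity_

        yte = labels[te] == positive_class
        if yte.all() or not yte.any():
            warnings.append(f"fold {k}: single-class test fold, test metrics missing")
            test_auc = test_sens = test_spec = None
        else:
            dte = clf.decision_function(F[te])
            test_auc = float(roc_auc_score(yte, dte))
            test_sens, test_spec = _sens_spec(clf.predict(F[te]), yte, positive_class)
        folds.append(CVFold(
            fold_index=k, l_selected=int(clf.l_star_),
            train_auc=train_auc, train_sensitivity=train_sens,
            train_specificity=train_spec,
            test_auc=test_auc, test_sensitivity=test_sens,
            test_specificity=test_spec,
            test_index=[int(i) for i in te]))

    means: dict[str, float] = {}
    ci: dict[str, list[float]] = {}
    fields_ = ("l_selected", "train_auc", "train_sensitivity", "train_specificity",
               "test_auc", "test_sensitivity", "test_specificity")
    for name in fields_:
        vals = np.array([getattr(f, name) for f in folds
                         if getattr(f, name) is not None], dtype=float)
        if vals.size == 0:
            continue
        means[name] = float(vals.mean())
        if vals.size > 1:
            half = stats.t.ppf(0.975, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size)
            ci[name] = [float(vals.mean() - half), float(vals.mean() + half)]
        else:
            ci[name] = [means[name], means[name]]
    return folds, means, ci, warnings


MARKER_ORDER = ("TIR", "mean_glucose", "SD", "MAGE", "CV")
_METRIC_INDEX = {"mean_glucose": 0, "SD": 1, "CV": 2, "TIR": 3, "MAGE": 4}


def compare_markers(cohort, F=None, l_min: int = 2, l_max: int = 130,
                    l_star: int | None = None, metrics_matrix=None,
                    positive_class: str = "LADA") -> ClassificationReport:
    """Head-to-head ROC comparison of F_d(l*) and the five classical metrics,
    plus the Spearman correlation matrix of every marker against FCP/2hCP and
    Cohen's kappa of the thresholded F_d(l*) against the clinical diagnosis.
    """
    labels = cohort.labels
    if F is None:
        F = profile_matrix(cohort.traces, l_min, l_max)
    F = np.asarray(F, dtype=float)
    scales = np.arange(l_min, l_max + 1)

    if l_star is None:
        sel = ScaleSelector(scales=scales).fit(F, cohort.fcp)
        l_star, r_star = sel.l_star_, sel.r_star_
    else:
        if l_star not in scales:
            raise InputError(f"l_star {l_star} outside scale range")
        r_star = None
    fd = F[:, int(np.searchsorted(scales, l_star))]

    M = (np.asarray(metrics_matrix, dtype=float) if metrics_matrix is not None
         else GlycemicMetricsExtractor().fit_transform(cohort.traces))
    marker_scores = {f"F_d({l_star})": fd}
    for name in MARKER_ORDER:
        marker_scores[name] = M[:, _METRIC_INDEX[name]]

    markers = []
    correlations = {}
    for name, scores in marker_scores.items():
        markers.append(roc_analysis(scores, labels, positive_class, marker_name=name))
        correlations[name] = {"fcp": spearman(scores, cohort.fcp),
                              "c2h": spearman(scores, cohort.c2h)}
    if r_star is None:
        r_star = correlations[f"F_d({l_star})"]["fcp"]

    thr = YoudenThresholdClassifier(positive_label=positive_class).fit(fd, labels)
    kappa = cohen_kappa(thr.predict(fd), labels)

    return ClassificationReport(
        markers=markers, correlations=correlations, kappa=float(kappa),
        l_star=int(l_star), r_star=float(r_star))
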