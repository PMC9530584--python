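"""ROC, Youden cutoff, kappa and the cross-validation protocol."""

import dataclasses
import json

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import cohen_kappa_score

from dffglu.classify import (
    DffScaleClassifier,
    YoudenThresholdClassifier,
    cohen_kappa,
    compare_markers,
    delong_auc_variance,
    roc_analysis,
    ten_fold_cv,
    youden_cutoff,
)
from dffglu.exceptions import InputError, UndefinedStatisticError

LADA3 = np.array([2.0, 1.9, 1.5])
T2DM3 = np.array([1.0, 1.2, 1.6])


def _scores_labels(pos, neg):
    scores = np.concatenate([pos, neg])
    labels = np.array(["LADA"] * len(pos) + ["T2DM"] * len(neg))
    return scores, labels


def pair_count_auc(pos, neg):
    """Exhaustive concordant-pair oracle (ties count one half)."""
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        s, y = _scores_labels([3.0, 4.0], [1.0, 2.0])
        assert roc_analysis(s, y).auc == 1.0

    def test_all_ties(self):
        s, y = _scores_labels([1.0, 1.0], [1.0, 1.0])
        assert roc_analysis(s, y).auc == 0.5

    def test_three_vs_three_worked_example(self):
        s, y = _scores_labels(LADA3, T2DM3)
        assert roc_analysis(s, y).auc == pytest.approx(8 / 9)

    def test_matches_pair_counting_on_random_cohorts(self, rng):
        for _ in range(40):
            m = int(rng.integers(2, 21))
            n = int(rng.integers(2, 21))
            pos = np.round(rng.normal(1, 1, m), 1)  # rounding forces ties
            neg = np.round(rng.normal(0, 1, n), 1)
            s, y = _scores_labels(pos, neg)
            res = roc_analysis(s, y)
            oracle = pair_count_auc(pos, neg)
            oracle = max(oracle, 1 - oracle)  # orientation keeps AUC >= 0.5
            assert res.auc == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_increasing_transform(self, rng):
        pos, neg = rng.normal(1, 1, 15), rng.normal(0, 1, 20)
        s, y = _scores_labels(pos, neg)
        assert roc_analysis(np.exp(s), y).auc == pytest.approx(roc_analysis(s, y).auc)

    def test_ci_brackets_auc_and_single_class_errors(self, rng):
        s, y = _scores_labels(rng.normal(1, 1, 10), rng.normal(0, 1, 10))
        res = roc_analysis(s, y)
        assert res.auc_ci_low <= res.auc <= res.auc_ci_high
        with pytest.raises(InputError):
            roc_analysis(s, np.array(["LADA"] * 20))

    def test_delong_variance_positive_and_shrinks(self, rng):
        small = delong_auc_variance(rng.normal(1, 1, 10), rng.normal(0, 1, 10))[1]
        large = delong_auc_variance(rng.normal(1, 1, 200), rng.normal(0, 1, 200))[1]
        assert 0 < large < small


class TestYouden:
    def test_worked_example_tie_breaks_to_higher_specificity(self):
        s, y = _scores_labels(LADA3, T2DM3)
        cutoff, sens, spec = youden_cutoff(s, y)
        assert cutoff == pytest.approx(1.75)
        assert sens == pytest.approx(100 * 2 / 3)
        assert spec == pytest.approx(100.0)

    def test_perfect_separation_midpoint(self):
        s, y = _scores_labels([3.0, 4.0], [1.0, 2.0])
        cutoff, sens, spec = youden_cutoff(s, y)
        assert cutoff == pytest.approx(2.5)
        assert (sens, spec) == (100.0, 100.0)

    def test_translation_equivariance(self, rng):
        pos, neg = rng.normal(1, 1, 12), rng.normal(0, 1, 12)
        s, y = _scores_labels(pos, neg)
        c0, se0, sp0 = youden_cutoff(s, y)
        c1, se1, sp1 = youden_cutoff(s + 10.0, y)
        assert c1 == pytest.approx(c0 + 10.0)
        assert (se1, sp1) == (se0, sp0)


class TestKappa:
    def test_perfect_agreement(self):
        y = np.array(["LADA", "T2DM"] * 5)
        assert cohen_kappa(y, y) == 1.0

    def test_twelve_patient_confusion_matrix(self):
        # TP=5, FN=1, FP=1, TN=5: p_o = 10/12, p_e = 1/2, kappa = 2/3
        actual = ["LADA"] * 6 + ["T2DM"] * 6
        pred = ["LADA"] * 5 + ["T2DM"] + ["LADA"] + ["T2DM"] * 5
        assert cohen_kappa(pred, actual) == pytest.approx(2 / 3)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.choice(["LADA", "T2DM"], 1000)
        b = rng.choice(["LADA", "T2DM"], 1000)
        assert abs(cohen_kappa(a, b)) < 0.1

    def test_matches_sklearn_cross_check(self, rng):
        for _ in range(10):
            a = rng.choice(["LADA", "T2DM"], 30)
            b = rng.choice(["LADA", "T2DM"], 30)
            if len(np.unique(a)) * len(np.unique(b)) == 1 and a[0] == b[0]:
                continue
            assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_bounded_by_observed_agreement(self, rng):
        for _ in range(10):
            a = rng.choice(["LADA", "T2DM"], 40)
            b = rng.choice(["LADA", "T2DM"], 40)
            try:
                k = cohen_kappa(a, b)
            except UndefinedStatisticError:
                continue
            assert k <= np.mean(a == b) + 1e-12

    def test_degenerate_chance_agreement_errors(self):
        with pytest.raises(UndefinedStatisticError):
            cohen_kappa(["LADA"] * 4, ["LADA"] * 4)


class TestThresholdClassifier:
    def test_orientation_and_prediction(self):
        s, y = _scores_labels(LADA3, T2DM3)
        clf = YoudenThresholdClassifier(positive_label="LADA").fit(s, y)
        assert clf.orientation_ == "higher"
        assert clf.cutoff_original_units_ == pytest.approx(1.75)
        np.testing.assert_array_equal(
            clf.predict(np.array([1.9, 1.0])), ["LADA", "T2DM"])

    def test_lower_orientation(self):
        # positive class sits on the LOW side (like TIR)
        s, y = _scores_labels([1.0, 1.2], [3.0, 3.5])
        clf = YoudenThresholdClassifier(positive_label="LADA").fit(s, y)
        assert clf.orientation_ == "lower"
        np.testing.assert_array_equal(
            clf.predict(np.array([0.5, 5.0])), ["LADA", "T2DM"])

    def test_cloneable(self):
        clf = DffScaleClassifier(scales=[2, 3], positive_label="LADA")
        assert clone(clf).get_params() == clf.get_params()


class TestTenFoldCV:
    def test_partition_and_stratification(self, small_cohort, small_F):
        folds, means, ci, warn = ten_fold_cv(small_cohort, F=small_F, seed=3)
        idx = np.concatenate([f.test_index for f in folds])
        assert sorted(idx.tolist()) == list(range(len(small_cohort)))
        labels = small_cohort.labels
        for lab in ("LADA", "T2DM"):
            counts = [np.sum(labels[f.test_index] == lab) for f in folds]
            assert max(counts) - min(counts) <= 1
        assert not warn

    def test_seed_determinism_byte_identical(self, small_cohort, small_F, tmp_path):
        import dffglu.io as dio
        payloads = []
        for _ in range(2):
            folds, means, ci, warn = ten_fold_cv(small_cohort, F=small_F, seed=5)
            rep = dataclasses.asdict(folds[0])
            payloads.append(json.dumps(
                {"folds": [dataclasses.asdict(f) for f in folds],
                 "means": means, "ci": ci}, sort_keys=True))
        assert payloads[0] == payloads[1]

    def test_means_are_fold_averages(self, small_cohort, small_F):
        folds, means, ci, _ = ten_fold_cv(small_cohort, F=small_F, seed=3)
        assert means["test_auc"] == pytest.approx(
            np.mean([f.test_auc for f in folds]))
        assert means["l_selected"] == pytest.approx(
            np.mean([f.l_selected for f in folds]))

    def test_no_gross_overfit_single_tuned_parameter(self, default_cohort, default_F):
        _, means, _, _ = ten_fold_cv(default_cohort, F=default_F, seed=0)
        assert abs(means["train_auc"] - means["test_auc"]) < 0.05


class TestCompareMarkers:
    def test_fd_wins_when_other_markers_are_shuffled(self, small_cohort, small_F, rng):
        from dffglu.metrics import GlycemicMetricsExtractor
        M = GlycemicMetricsExtractor().fit_transform(small_cohort.traces)
        M = M[rng.permutation(len(M))]  # destroy the other markers' signal
        rep = compare_markers(small_cohort, F=small_F, metrics_matrix=M)
        fd_auc = rep.markers[0].auc
        assert all(fd_auc > m.auc for m in rep.markers[1:])

    def test_correlation_matrix_bounded(self, small_cohort, small_F):
        rep = compare_markers(small_cohort, F=small_F)
        for entry in rep.correlations.values():
            assert -1 <= entry["fcp"] <= 1
            assert -1 <= entry["c2h"] <= 1
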