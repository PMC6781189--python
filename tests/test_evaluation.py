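"""Diagnostic metrics, ROC/AUC and CAM localization scoring."""

import numpy as np
import pytest

from lesioncam.evaluation import (LocalizationResult, confusion_metrics,
                                  correct_ratio, evaluation_totals,
                                  localize_from_cam, overlap_over_truth,
                                  overlap_ratio, roc_curve_auc)
from lesioncam.gradcam import CAMMap


def concordance_auc(scores, labels):
    """O(n^2) pairwise-concordance AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_all_correct(self):
        m = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0], positive=1)
        assert m.sensitivity == 100.0 and m.specificity == 100.0

    def test_hand_computed_counts(self):
        # tp=3, fn=1, tn=2, fp=2
        truth = [1, 1, 1, 1, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 1, 1, 0, 0]
        m = confusion_metrics(pred, truth, positive=1)
        assert (m.tp, m.fn, m.tn, m.fp) == (3, 1, 2, 2)
        assert m.sensitivity == pytest.approx(75.0)
        assert m.specificity == pytest.approx(50.0)
        assert m.ppv == pytest.approx(60.0)
        assert m.npv == pytest.approx(100 * 2 / 3)

    def test_swapping_positive_class_swaps_rates(self):
        truth = [1, 1, 1, 0, 0, 1, 0, 0]
        pred = [1, 0, 1, 0, 1, 1, 0, 0]
        m1 = confusion_metrics(pred, truth, positive=1)
        m0 = confusion_metrics(pred, truth, positive=0)
        assert m1.sensitivity == m0.specificity
        assert m1.ppv == m0.npv

    def test_undefined_rates_are_none_not_zero(self):
        m = confusion_metrics([0, 0], [0, 0], positive=1)
        assert m.sensitivity is None and m.ppv is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [], positive=1)

    def test_rates_within_percentage_bounds(self, rng):
        for _ in range(20):
            truth = rng.integers(0, 2, 30)
            pred = rng.integers(0, 2, 30)
            if len(np.unique(truth)) < 2:
                continue
            m = confusion_metrics(pred.tolist(), truth.tolist(), positive=1)
            for v in (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy):
                if v is not None:
                    assert 0.0 <= v <= 100.0


class TestROC:
    def test_perfect_separation(self):
        r = roc_curve_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == pytest.approx(1.0)

    def test_uninformative_scores_give_half(self):
        r = roc_curve_auc([0.5] * 10, [1, 0] * 5)
        assert r.auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self, rng):
        r = roc_curve_auc(rng.random(50), rng.integers(0, 2, 50))
        assert r.fpr[0] == 0 and r.tpr[0] == 0
        assert r.fpr[-1] == 1 and r.tpr[-1] == 1
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_matches_concordance_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=50)
            labels = rng.integers(0, 2, 50)
            if len(np.unique(labels)) < 2:
                continue
            r = roc_curve_auc(scores, labels)
            assert r.auc == pytest.approx(concordance_auc(scores, labels),
                                          abs=1e-12)

    def test_pooled_folds_equal_concatenation(self, rng):
        folds_s = [rng.random(20) for _ in range(3)]
        folds_l = [rng.integers(0, 2, 20) for _ in range(3)]
        pooled = roc_curve_auc(folds_s, folds_l)
        concat = roc_curve_auc(np.concatenate(folds_s), np.concatenate(folds_l))
        assert pooled.auc == pytest.approx(concat.auc)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc([0.1, 0.2], [1, 1])


def _norm_cam(values):
    return CAMMap(np.asarray(values, dtype=float), np.zeros(1), 0,
                  normalized=True)


class TestLocalize:
    def test_binary_cam_is_fixed_point(self):
        mask = np.zeros((8, 8))
        mask[2:5, 2:5] = 1.0
        region = localize_from_cam(_norm_cam(mask))
        assert np.array_equal(region, mask.astype(bool))

    def test_all_zero_cam_gives_empty_region(self):
        region = localize_from_cam(_norm_cam(np.zeros((6, 6))))
        assert not region.any()

    def test_largest_component_kept(self):
        cam = np.zeros((10, 10))
        cam[0:5, 0:6] = 1.0      # area 30
        cam[8:10, 0:5] = 1.0     # area 10
        region = localize_from_cam(_norm_cam(cam))
        assert region.sum() == 30
        assert region[:5, :6].all()

    def test_unnormalized_cam_rejected(self):
        cam = CAMMap(np.ones((4, 4)), np.zeros(1), 0, normalized=False)
        with pytest.raises(ValueError):
            localize_from_cam(cam)


class TestOverlap:
    def test_identical_nonempty_masks(self):
        m = np.zeros((6, 6), bool)
        m[1:4, 1:4] = True
        assert overlap_ratio(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert overlap_ratio(a, b) == 0.0

    def test_contained_block_counting(self):
        t = np.zeros((8, 8), bool)
        t[0:4, 0:2] = True          # 4x2 block
        a = np.zeros((8, 8), bool)
        a[0:2, 0:2] = True          # contained 2x2 block
        assert overlap_ratio(a, t) == pytest.approx(4 / 8)

    def test_both_empty_counts_as_correct_non_activation(self):
        e = np.zeros((4, 4), bool)
        assert overlap_ratio(e, e) == 1.0

    def test_empty_vs_nonempty_is_zero(self):
        e = np.zeros((4, 4), bool)
        t = e.copy()
        t[0, 0] = True
        assert overlap_ratio(e, t) == 0.0
        assert overlap_ratio(t, e) == 0.0

    def test_bounds_on_random_masks(self, rng):
        for _ in range(50):
            a = rng.random((8, 8)) > 0.5
            t = rng.random((8, 8)) > 0.5
            assert 0.0 <= overlap_ratio(a, t) <= 1.0

    def test_intersection_over_truth_alternative(self):
        t = np.zeros((8, 8), bool)
        t[0:4, 0:2] = True
        a = np.zeros((8, 8), bool)
        a[0:2, 0:2] = True
        assert overlap_over_truth(a, t) == pytest.approx(0.5)


class TestCorrectRatio:
    def _results(self, overlaps):
        return [LocalizationResult(str(i), np.zeros((2, 2), bool), o, o >= 0.5)
                for i, o in enumerate(overlaps)]

    def test_all_perfect(self):
        assert correct_ratio(self._results([1.0] * 5)) == 1.0

    def test_half_above_cutoff(self):
        assert correct_ratio(self._results([0.6, 0.4])) == 0.5

    def test_constructed_fraction(self, rng):
        overlaps = list(rng.uniform(0.5, 1.0, 190)) + list(rng.uniform(0, 0.49, 10))
        assert correct_ratio(self._results(overlaps)) == pytest.approx(0.95)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            correct_ratio([])


class TestEvaluationTotals:
    def test_depth_task_accounting(self):
        assert evaluation_totals(5, 300, 90) == 1590

    def test_detection_task_accounting(self):
        assert evaluation_totals(5, 660, 90) == 3390

    def test_degenerate_zero(self):
        assert evaluation_totals(1, 0, 0) == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            evaluation_totals(-1, 10, 0)
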