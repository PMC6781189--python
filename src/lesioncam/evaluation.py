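"""Diagnostic metrics and CAM-based lesion localization scoring.

Classification is scored with sensitivity/specificity/PPV/NPV (percent)
and ROC AUC pooled over cross-validation folds.  Localization extracts a
suspected-lesion region from the normalised CAM (threshold at half the
map maximum, keep the largest connected component) and scores it against
the ground-truth mask with intersection-over-union; the correct ratio is
the fraction of images reaching 0.5 overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from sklearn.metrics import roc_curve as _sk_roc_curve

from .gradcam import CAMMap

__all__ = ["DiagnosticMetrics", "ROCResult", "LocalizationResult",
           "confusion_metrics", "roc_curve_auc", "localize_from_cam",
           "overlap_ratio", "overlap_over_truth", "correct_ratio",
           "evaluation_totals"]


@dataclass
class DiagnosticMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None


def _rate(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def confusion_metrics(predicted, truth, positive) -> DiagnosticMetrics:
    """Binary confusion counts and percentage rates.

    Rates with an empty denominator are reported as None (not 0).
    """
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("label sequences differ in length")
    if not predicted:
        raise ValueError("empty input")
    tp = sum(1 for p, t in zip(predicted, truth) if p == positive and t == positive)
    fp = sum(1 for p, t in zip(predicted, truth) if p == positive and t != positive)
    tn = sum(1 for p, t in zip(predicted, truth) if p != positive and t != positive)
    fn = sum(1 for p, t in zip(predicted, truth) if p != positive and t == positive)
    return DiagnosticMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_rate(tp, tp + fn), specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp), npv=_rate(tn, tn + fn),
        accuracy=_rate(tp + tn, tp + fp + tn + fn))


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve_auc(scores, labels) -> ROCResult:
    """ROC curve and trapezoidal AUC for positive-class scores.

    To pool several folds (the study sums all cross-validation folds),
    pass lists of per-fold arrays; they are concatenated before the curve
    is built, which is equivalent to scoring the pooled set directly.
    """
    def pool(seq):
        if isinstance(seq, (list, tuple)) and len(seq) and np.ndim(seq[0]) == 1:
            return np.concatenate([np.asarray(s) for s in seq])
        return np.asarray(seq)

    scores = pool(scores).astype(np.float64)
    labels = pool(labels).astype(int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


@dataclass
class LocalizationResult:
    image_id: str
    activated_region: np.ndarray
    overlap: float
    correct: bool


def localize_from_cam(cam: CAMMap, threshold: float = 0.5) -> np.ndarray:
    """Binarise a normalised CAM at ``threshold`` x map-maximum and keep the
    largest 8-connected component as the suspected lesion region."""
    if not cam.normalized:
        raise ValueError("localize_from_cam expects a normalised CAM")
    values = cam.values
    if values.max() <= 0:
        return np.zeros_like(values, dtype=bool)
    binary = values >= threshold * values.max()
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(values, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(sizes.argmax()) + 1)


def overlap_ratio(activated: np.ndarray, truth: np.ndarray) -> float:
    """Intersection-over-union of the activated region and the truth mask.

    Both empty counts as perfect non-activation (1.0); one empty side
    against a non-empty one scores 0.
    """
    activated = np.asarray(activated, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if activated.shape != truth.shape:
        raise ValueError("shape mismatch")
    union = (activated | truth).sum()
    if union == 0:
        return 1.0
    return float((activated & truth).sum() / union)


def overlap_over_truth(activated: np.ndarray, truth: np.ndarray) -> float:
    """Alternative overlap: intersection over the truth-mask area."""
    activated = np.asarray(activated, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if activated.shape != truth.shape:
        raise ValueError("shape mismatch")
    t = truth.sum()
    if t == 0:
        return 1.0 if not activated.any() else 0.0
    return float((activated & truth).sum() / t)


def correct_ratio(results: list[LocalizationResult], cutoff: float = 0.5) -> float:
    """Fraction of localization results whose overlap reaches the cutoff."""
    if not results:
        raise ValueError("empty result list")
    return float(np.mean([r.overlap >= cutoff for r in results]))


def evaluation_totals(n_groups: int, per_group_test_size: int, n_extra: int) -> int:
    """Total images evaluated: rotation groups x fixed test size + held-out
    extras (the study's accounting: 5 x 300 + 90 and 5 x 660 + 90)."""
    if min(n_groups, per_group_test_size, n_extra) < 0:
        raise ValueError("counts must be non-negative")
    return n_groups * per_group_test_size + n_extra
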