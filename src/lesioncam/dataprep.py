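"""Image quality filtering and patient-level five-fold cross-validation.

The study excluded frames with motion blur / defocus and halation before
randomising *patients* (not images) into five folds, then rotated the folds
3:1:1 into train/validation/test so that each fold serves as the test set
exactly once.  Keeping all of a patient's frames in one fold is what
prevents near-duplicate frames from leaking across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import laplace

from .synthdata import LabeledImage, SyntheticCohort

__all__ = ["QualityThresholds", "QualityReport", "FoldAssignment", "CVGroup",
           "quality_scores", "filter_images", "assign_folds",
           "cross_validation_groups", "sample_fixed_test_set"]


@dataclass(frozen=True)
class QualityThresholds:
    """Exclusion rules: a frame is dropped when its Laplacian-variance blur
    score falls below ``blur_min`` or its near-saturated fraction exceeds
    ``halation_max``.  ``None`` disables a rule."""

    blur_min: float | None = None
    halation_max: float | None = None


@dataclass
class QualityReport:
    image_id: str
    blur_score: float
    halation_fraction: float
    excluded: bool
    reasons: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded must be true iff reasons is non-empty")


def quality_scores(image: LabeledImage,
                   thresholds: QualityThresholds = QualityThresholds()
                   ) -> QualityReport:
    """Blur and halation scores for one frame.

    blur_score is the variance of a discrete Laplacian of the luminance
    channel (sharp frames have strong high-frequency response); the
    halation fraction counts pixels with all three channels >= 0.98.
    """
    px = np.asarray(image.pixels, dtype=np.float64)
    if px.size == 0:
        raise ValueError("empty image")
    lum = px @ np.array([0.299, 0.587, 0.114])
    blur = float(laplace(lum).var())
    halation = float(np.all(px >= 0.98, axis=-1).mean())
    reasons: set[str] = set()
    if thresholds.blur_min is not None and blur < thresholds.blur_min:
        reasons.add("blur")
    if thresholds.halation_max is not None and halation > thresholds.halation_max:
        reasons.add("halation")
    return QualityReport(image_id=image.image_id, blur_score=blur,
                         halation_fraction=halation,
                         excluded=bool(reasons), reasons=reasons)


def filter_images(cohort: SyntheticCohort, thresholds: QualityThresholds
                  ) -> tuple[SyntheticCohort, pd.DataFrame]:
    """Split a cohort into retained images and an exclusion log.

    The log has one row per removed image (image_id, patient_id, scores,
    semicolon-joined reasons); retained + excluded = input.
    """
    for t in (thresholds.blur_min, thresholds.halation_max):
        if t is not None and not np.isfinite(t):
            raise ValueError("thresholds must be finite")
    kept: list[LabeledImage] = []
    rows = []
    for im in cohort.images:
        rep = quality_scores(im, thresholds)
        if rep.excluded:
            rows.append({"image_id": im.image_id, "patient_id": im.patient_id,
                         "blur_score": rep.blur_score,
                         "halation_fraction": rep.halation_fraction,
                         "reasons": ";".join(sorted(rep.reasons))})
        else:
            kept.append(im)
    kept_ids = {im.image_id for im in kept}
    patients = {pid: [iid for iid in ids if iid in kept_ids]
                for pid, ids in cohort.patients.items()}
    patients = {pid: ids for pid, ids in patients.items() if ids}
    log = pd.DataFrame(rows, columns=["image_id", "patient_id", "blur_score",
                                      "halation_fraction", "reasons"])
    retained = SyntheticCohort(images=kept, patients=patients,
                               seed=cohort.seed,
                               generation_params=cohort.generation_params)
    return retained, log


@dataclass
class FoldAssignment:
    folds: dict[str, int]     # patient_id -> fold index
    seed: int
    k: int = 5

    def patients_in(self, fold: int) -> list[str]:
        return [p for p, f in self.folds.items() if f == fold]

    def image_fold(self, cohort: SyntheticCohort) -> dict[str, int]:
        """Every image inherits its patient's fold."""
        return {iid: self.folds[pid]
                for pid, ids in cohort.patients.items() for iid in ids}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.folds.items()),
                            columns=["patient_id", "fold"])


def assign_folds(patient_ids: list[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Shuffle patients by seed and deal them round-robin into k folds."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if len(ids) < k:
        raise ValueError(f"need at least {k} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(sorted(ids)))
    return FoldAssignment(folds={pid: i % k for i, pid in enumerate(order)},
                          seed=seed, k=k)


@dataclass(frozen=True)
class CVGroup:
    group_index: int
    train_folds: tuple[int, int, int]
    val_fold: int
    test_fold: int

    def __post_init__(self) -> None:
        all_folds = set(self.train_folds) | {self.val_fold, self.test_fold}
        if all_folds != set(range(5)) or len(self.train_folds) != 3:
            raise ValueError("train/val/test folds must partition {0..4} as 3:1:1")


def cross_validation_groups(k: int = 5) -> list[CVGroup]:
    """The five 3:1:1 rotations: group g trains on folds (g, g+1, g+2),
    validates on g+3 and tests on g+4 (mod 5)."""
    if k != 5:
        raise ValueError("the cross-validation design is fixed at k=5 folds")
    return [CVGroup(group_index=g,
                    train_folds=(g % 5, (g + 1) % 5, (g + 2) % 5),
                    val_fold=(g + 3) % 5, test_fold=(g + 4) % 5)
            for g in range(5)]


def split_cohort(cohort: SyntheticCohort, assignment: FoldAssignment,
                 group: CVGroup) -> dict[str, list[LabeledImage]]:
    """Materialise the train/val/test image lists for one CV group."""
    part: dict[str, list[LabeledImage]] = {"train": [], "val": [], "test": []}
    train = set(group.train_folds)
    for im in cohort.images:
        f = assignment.folds[im.patient_id]
        if f in train:
            part["train"].append(im)
        elif f == group.val_fold:
            part["val"].append(im)
        else:
            part["test"].append(im)
    return part


def sample_fixed_test_set(images: list[LabeledImage], n_per_class: int,
                          rng: np.random.Generator,
                          classes: list[str] | None = None) -> list[LabeledImage]:
    """Draw exactly n_per_class images per class, without replacement.

    Mirrors the study's fixed-size test sampling (e.g. 150 + 150 frames for
    the depth task) which equalises test sets across rotation groups.
    """
    by_class: dict[str, list[LabeledImage]] = {}
    for im in images:
        by_class.setdefault(im.class_label, []).append(im)
    use = classes if classes is not None else sorted(by_class)
    out: list[LabeledImage] = []
    for cls in use:
        pool = by_class.get(cls, [])
        if len(pool) < n_per_class:
            raise ValueError(
                f"class {cls!r} has only {len(pool)} test images; "
                f"{n_per_class} requested")
        idx = rng.choice(len(pool), size=n_per_class, replace=False)
        out.extend(pool[i] for i in sorted(idx))
    return out
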