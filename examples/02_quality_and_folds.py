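"""Quality filtering and patient-level five-fold cross-validation.

Frames failing blur/halation rules are excluded first; the remaining
patients are dealt into five folds and rotated 3:1:1 into
train/validation/test so each fold is the test set exactly once.
"""

import numpy as np

from lesioncam import (QualityThresholds, assign_folds,
                       cross_validation_groups, filter_images,
                       generate_cohort, quality_scores, split_cohort)

cohort = generate_cohort(n_patients=25, class_mix=(0.5, 0.25, 0.25),
                         image_side=64, seed=3)

# calibrate the blur rule on the cohort itself: drop the softest decile
blur = np.array([quality_scores(im).blur_score for im in cohort.images])
print(f"blur scores: min {blur.min():.4f}, median {np.median(blur):.4f}, "
      f"max {blur.max():.4f}")
thresholds = QualityThresholds(blur_min=float(np.quantile(blur, 0.1)),
                               halation_max=0.2)
retained, log = filter_images(cohort, thresholds)
print(f"retained {len(retained.images)} / {len(cohort.images)} frames "
      f"({len(log)} excluded for quality)")

assignment = assign_folds(sorted(retained.patients), k=5, seed=3)
for group in cross_validation_groups():
    parts = split_cohort(retained, assignment, group)
    pat = {k: {im.patient_id for im in v} for k, v in parts.items()}
    leak = (pat["train"] & pat["test"]) | (pat["train"] & pat["val"])
    print(f"group {group.group_index}: train folds {group.train_folds}, "
          f"val {group.val_fold}, test {group.test_fold} — "
          f"{len(parts['train'])}/{len(parts['val'])}/{len(parts['test'])} "
          f"frames, patient leakage: {sorted(leak)}")

# Patient leakage is empty for every rotation: all frames of one patient
# stay on one side of each split, which is what makes the test folds honest.
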