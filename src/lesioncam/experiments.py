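"""End-to-end experiment presets wiring the modules together.

Two tasks mirror the study's two models: ``detection`` (lesion vs
non-lesion frames) and ``depth`` (mucosal T1a vs submucosal T1b).  The
headline experiment trains the same seeded backbone twice — once with
plain cross-entropy, once with the lesion-based composite loss — on one
cross-validation group of a synthetic cohort, and compares test AUC and
the CAM correct ratio at 0.5 overlap between the two modes.
"""

from __future__ import annotations

import numpy as np

from . import dataprep, evaluation, gradcam, synthdata, training
from .backbone import ModelConfig, TrainingConfig, build_model, predict

__all__ = ["TASKS", "task_label_map", "localization_results",
           "evaluate_model", "run_mode_comparison"]

TASKS = ("detection", "depth")


def task_label_map(task: str):
    """Class-name -> integer label for a task (None drops the image)."""
    if task == "detection":
        return lambda c: 0 if c == "nonEGC" else 1
    if task == "depth":
        return lambda c: {"T1a": 0, "T1b": 1}.get(c)
    raise ValueError(f"unknown task {task!r}; choose from {TASKS}")


def localization_results(model, images, target_class: int = 1, *,
                         cam_threshold: float = 0.5, overlap_cutoff: float = 0.5,
                         batch: int = 32) -> list[evaluation.LocalizationResult]:
    """Score CAM localization on images that carry a ground-truth mask."""
    scored = [im for im in images if im.lesion_mask is not None]
    out: list[evaluation.LocalizationResult] = []
    dtype = model.params[0].dtype
    for start in range(0, len(scored), batch):
        chunk = scored[start:start + batch]
        x = np.asarray([np.transpose(im.pixels, (2, 0, 1)) for im in chunk],
                       dtype=dtype)
        _, a, da = model.score_gradients(x, target_class)
        raw, alpha = gradcam.cam_from_features(a.astype(np.float64),
                                               da.astype(np.float64))
        for i, im in enumerate(chunk):
            cam = gradcam.CAMMap(values=raw[i], channel_weights=alpha[i],
                                 target_class=target_class)
            cam = gradcam.normalize_cam(cam)
            cam = gradcam.upsample_cam(cam, im.pixels.shape[:2])
            region = evaluation.localize_from_cam(cam, threshold=cam_threshold)
            ov = evaluation.overlap_ratio(region, im.lesion_mask)
            out.append(evaluation.LocalizationResult(
                image_id=im.image_id, activated_region=region, overlap=ov,
                correct=ov >= overlap_cutoff))
    return out


def evaluate_model(model, test_images, task: str, *, cam_threshold: float = 0.5,
                   overlap_cutoff: float = 0.5) -> dict:
    """Classification metrics plus CAM localization scores on a test set."""
    label_of = task_label_map(task)
    labelled = [im for im in test_images if label_of(im.class_label) is not None]
    x, y, _ = training.prepare_arrays(labelled, label_of,
                                      dtype=model.params[0].dtype)
    probs = []
    for start in range(0, len(x), 64):
        probs.append(predict(model, x[start:start + 64]))
    probs = np.concatenate(probs)
    pred = probs.argmax(axis=1)
    cm = evaluation.confusion_metrics(pred.tolist(), y.tolist(), positive=1)
    roc = evaluation.roc_curve_auc(probs[:, 1], y) if len(np.unique(y)) > 1 else None
    loc = localization_results(model, labelled, target_class=1,
                               cam_threshold=cam_threshold,
                               overlap_cutoff=overlap_cutoff)
    res = {
        "n_test": len(labelled),
        "auc": roc.auc if roc else None,
        "sensitivity": cm.sensitivity, "specificity": cm.specificity,
        "ppv": cm.ppv, "npv": cm.npv, "accuracy": cm.accuracy,
        "scores": probs[:, 1], "labels": y,
        "localization": loc,
        "correct_ratio": (evaluation.correct_ratio(loc, overlap_cutoff)
                          if loc else None),
    }
    return res


def run_mode_comparison(seed: int, *, task: str = "detection",
                        n_patients: int = 120, image_side: int = 64,
                        class_mix=(0.50, 0.25, 0.25),
                        images_per_patient=(3, 6),
                        architecture: str = "vgg-style", width: int = 8,
                        epochs: int = 15, learning_rate: float = 3e-3,
                        batch_size: int = 16, w_ce: float = 1.0,
                        w_cam: float = 1.0, group_index: int = 0) -> dict:
    """Train plain vs lesion mode on one CV group of a synthetic cohort.

    Both models start from the identical seeded initialisation, see the
    identical batches and get the identical modest training budget; only
    the objective differs.  Returns per-mode test metrics plus the cohort
    bookkeeping.
    """
    cohort = synthdata.generate_cohort(
        n_patients=n_patients, class_mix=class_mix,
        images_per_patient=images_per_patient, image_side=image_side,
        seed=seed)
    assignment = dataprep.assign_folds(sorted(cohort.patients), k=5,
                                       seed=seed + 1)
    group = dataprep.cross_validation_groups()[group_index]
    split = dataprep.split_cohort(cohort, assignment, group)

    label_of = task_label_map(task)
    data = {
        name: training.prepare_arrays(
            [im for im in split[name] if label_of(im.class_label) is not None],
            label_of)
        for name in ("train", "val")
    }
    model_cfg = ModelConfig(architecture=architecture, n_classes=2,
                            input_side=image_side, width=width, seed=seed + 2)

    results: dict = {"seed": seed, "task": task,
                     "n_images": len(cohort.images),
                     "n_patients": n_patients,
                     "group": group_index, "modes": {}}
    for mode in ("plain", "lesion"):
        model = build_model(model_cfg)
        cfg = TrainingConfig(loss_mode=mode, w_ce=w_ce, w_cam=w_cam,
                             learning_rate=learning_rate, epochs=epochs,
                             batch_size=batch_size, seed=seed + 3)
        model, history = training.train_model(model, data, cfg)
        ev = evaluate_model(model, split["test"], task)
        ev["history"] = history
        results["modes"][mode] = ev
    plain = results["modes"]["plain"]
    lesion = results["modes"]["lesion"]
    if plain["correct_ratio"] is not None and lesion["correct_ratio"] is not None:
        results["correct_ratio_gain"] = (lesion["correct_ratio"]
                                         - plain["correct_ratio"])
    return results
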