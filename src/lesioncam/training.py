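"""Plain cross-entropy and lesion-based composite training.

The lesion-based objective is a weighted sum of two terms,

    L = w_ce * CE(softmax(y), class)  +  w_cam * D(L^c_norm, M)

where L^c_norm is the max-normalised Grad-CAM map of the *true* class at
feature resolution and M the ground-truth lesion mask downsampled to the
same grid (all-zero for images without a lesion, so any activation on
non-lesion frames is penalised).  D is the mean squared difference by
default; a soft-Dice alternative is available via ``cam_loss='dice'``.

Backpropagation treats the pooled-gradient channel weights alpha_k and the
per-image normalising maximum as constants, so the localization term
shapes the feature maps A^k directly (a first-order treatment; see the
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import ModelHandle, TrainingConfig, make_optimizer
from .gradcam import downsample_mask

__all__ = ["LossValue", "TrainingHistory", "TrainingError", "cross_entropy",
           "cam_localization_loss", "composite_loss", "train_model",
           "prepare_arrays"]

_EPS = 1e-12


class TrainingError(RuntimeError):
    pass


@dataclass
class LossValue:
    total: float
    ce_term: float
    cam_term: float = 0.0


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)
    selected_epoch: int | None = None
    seed: int = 0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.epochs)


def cross_entropy(probs: np.ndarray, label: int) -> float:
    """-log p(true class) for one probability vector, clamped at 1e-12."""
    p = np.asarray(probs, dtype=np.float64)
    if not (0 <= label < p.shape[-1]):
        raise ValueError(f"label {label} out of range for {p.shape[-1]} classes")
    return float(-np.log(max(p[label], _EPS)))


def cam_localization_loss(cam: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared difference between a normalised CAM and a binary mask."""
    cam = np.asarray(cam, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if cam.shape != mask.shape:
        raise ValueError(f"shape mismatch: cam {cam.shape} vs mask {mask.shape}")
    if cam.min() < 0 or cam.max() > 1 + 1e-9:
        raise ValueError("cam must be normalised to [0, 1]")
    return float(np.mean((cam - mask) ** 2))


def composite_loss(ce_term: float, cam_term: float, config: TrainingConfig) -> LossValue:
    """Combine the two loss terms per the configured mode and weights."""
    if config.loss_mode == "plain":
        return LossValue(total=config.w_ce * ce_term, ce_term=ce_term, cam_term=0.0)
    total = config.w_ce * ce_term + config.w_cam * cam_term
    return LossValue(total=total, ce_term=ce_term, cam_term=cam_term)


# ---------------------------------------------------------------------------

def prepare_arrays(images, label_of, dtype=np.float32):
    """Stack LabeledImages into (X, y, M) arrays for training.

    ``label_of`` maps a class name to an integer (or None to drop the
    image).  M holds full-resolution masks as floats, all-zero where the
    image has none.
    """
    xs, ys, ms = [], [], []
    for im in images:
        lab = label_of(im.class_label)
        if lab is None:
            continue
        xs.append(np.transpose(im.pixels, (2, 0, 1)))
        ys.append(lab)
        side = im.pixels.shape[0]
        ms.append(im.lesion_mask.astype(np.float64) if im.lesion_mask is not None
                  else np.zeros((side, side)))
    if not xs:
        raise ValueError("no images after label mapping")
    return (np.asarray(xs, dtype=dtype), np.asarray(ys, dtype=np.int64),
            np.asarray(ms, dtype=dtype))


def _softmax(scores: np.ndarray) -> np.ndarray:
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def _batch_cam(model: ModelHandle, a: np.ndarray, y: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """True-class CAM training surrogate for a batch with cached features ``a``.

    Returns (pre, alpha): the unrectified weighted-sum map and the pooled
    channel weights.  The caller normalises ``pre`` into the surrogate map
    (see :class:`_CamScale`) and treats ``alpha`` and the normalising scale
    as constants in its backward pass.
    """
    n = a.shape[0]
    onehot = np.zeros((n, model.config.n_classes), dtype=a.dtype)
    onehot[np.arange(n), y] = 1.0
    g = model.head_backward(onehot, accumulate=False)
    alpha = g.mean(axis=(2, 3))
    pre = np.einsum("nk,nkuv->nuv", alpha, a)
    return pre, alpha


class _CamScale:
    """Detached normalising scale for the CAM training surrogate.

    Three pitfalls shape this.  Rectifying before the loss would zero the
    gradient wherever the map is negative, so the surrogate stays
    unrectified.  Normalising each frame by its own maximum rescales even a
    vanishing activation to unit magnitude, so a maskless frame could never
    satisfy its all-zero target and the penalty would erode features
    without end; hence one shared batch scale.  And a bare batch maximum
    still admits a death spiral — suppression shrinks the max, the 1/scale
    gradient grows, suppression accelerates — so the scale is floored at
    10% of the largest activation magnitude seen so far in the run.
    """

    def __init__(self) -> None:
        self.peak = 0.0

    def __call__(self, pre: np.ndarray) -> float:
        bmax = float(np.abs(pre).max())
        self.peak = max(self.peak, bmax)
        scale = max(bmax, 0.1 * self.peak)
        return scale if scale > 0 else 1.0


def _cam_loss_and_grad(cam: np.ndarray, target: np.ndarray, kind: str
                       ) -> tuple[float, np.ndarray]:
    """Per-batch localization loss and its gradient w.r.t. the normalised CAM."""
    n, u, v = cam.shape
    diff = cam - target
    if kind == "mse":
        loss = float(np.mean(diff ** 2))
        grad = 2.0 * diff / (n * u * v)
    else:  # soft dice, averaged over the batch
        eps = 1e-6
        num = 2.0 * (cam * target).sum(axis=(1, 2)) + eps
        den = (cam ** 2).sum(axis=(1, 2)) + (target ** 2).sum(axis=(1, 2)) + eps
        loss = float(np.mean(1.0 - num / den))
        grad = (-(2.0 * target * den[:, None, None]
                  - num[:, None, None] * 2.0 * cam)
                / (den ** 2)[:, None, None]) / n
    return loss, grad.astype(cam.dtype)


def train_model(model: ModelHandle, data: dict, config: TrainingConfig
                ) -> tuple[ModelHandle, TrainingHistory]:
    """Mini-batch training of the configured objective over one CV group.

    ``data`` maps 'train' and 'val' to (X, y, M) triples from
    :func:`prepare_arrays`.  In lesion mode every batch computes the
    true-class Grad-CAM and backpropagates the composite loss through the
    feature maps.  The model state achieving the lowest validation total
    loss is restored before returning.
    """
    x_tr, y_tr, m_tr = data["train"]
    x_va, y_va, m_va = data["val"]
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = make_optimizer(model, config.learning_rate)
    lesion = config.loss_mode == "lesion"
    u = v = model.config.input_side // model.downsampling
    mt_ds = _downsample_batch(m_tr, (u, v)) if lesion else None
    mv_ds = _downsample_batch(m_va, (u, v)) if lesion else None

    history = TrainingHistory(seed=config.seed)
    best = (np.inf, model.state(), None)
    cam_scale = _CamScale()
    n = len(x_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ce_sum = cam_sum = tot_sum = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            model.zero_grad()
            a = model.feature_maps(xb)
            scores = model.head_forward(a)
            probs = _softmax(scores.astype(np.float64))
            b = len(idx)
            ce = float(-np.log(np.maximum(probs[np.arange(b), yb], _EPS)).mean())
            onehot = np.zeros_like(probs)
            onehot[np.arange(b), yb] = 1.0
            dscores = ((probs - onehot) / b * config.w_ce).astype(scores.dtype)

            cam_term = 0.0
            da_cam = 0.0
            if lesion:
                pre, alpha = _batch_cam(model, a, yb)
                scale = cam_scale(pre)
                cam = pre.astype(np.float64) / scale
                cam_term, dcam = _cam_loss_and_grad(
                    cam, mt_ds[idx].astype(np.float64), config.cam_loss)
                dpre = dcam / scale
                da_cam = (alpha[:, :, None, None] * dpre[:, None, :, :]
                          * config.w_cam).astype(a.dtype)

            loss = composite_loss(ce, cam_term, config)
            if not np.isfinite(loss.total):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            da = model.head_backward(dscores, accumulate=True)
            if lesion:
                da = da + da_cam
            model.backward_from_features(da)
            opt.step()
            ce_sum += loss.ce_term
            cam_sum += loss.cam_term
            tot_sum += loss.total
            n_batches += 1

        val = _evaluate_objective(model, x_va, y_va, mv_ds, config,
                                  cam_scale=cam_scale)
        history.epochs.append({
            "epoch": epoch,
            "train_ce": ce_sum / n_batches,
            "train_cam": cam_sum / n_batches,
            "train_total": tot_sum / n_batches,
            "val_ce": val["ce"], "val_cam": val["cam"],
            "val_total": val["total"], "val_acc": val["acc"],
        })
        if val["total"] < best[0]:
            best = (val["total"], model.state(), epoch)

    if config.epochs > 0:
        model.load_state(best[1])
        history.selected_epoch = best[2]
    return model, history


def _downsample_batch(masks: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return np.stack([downsample_mask(m, shape) for m in masks])


def _evaluate_objective(model: ModelHandle, x: np.ndarray, y: np.ndarray,
                        m_ds: np.ndarray | None, config: TrainingConfig,
                        cam_scale: "_CamScale | None" = None,
                        chunk: int = 64) -> dict:
    ce_terms, cam_terms, correct = [], [], 0
    lesion = config.loss_mode == "lesion"
    for start in range(0, len(x), chunk):
        xb, yb = x[start:start + chunk], y[start:start + chunk]
        a = model.feature_maps(xb)
        scores = model.head_forward(a)
        probs = _softmax(scores.astype(np.float64))
        b = len(xb)
        ce_terms.append(-np.log(np.maximum(probs[np.arange(b), yb], _EPS)))
        correct += int((probs.argmax(axis=1) == yb).sum())
        if lesion:
            pre, _ = _batch_cam(model, a, yb)
            scale = max(float(np.abs(pre).max()),
                        0.1 * cam_scale.peak if cam_scale else 0.0) or 1.0
            cam = pre.astype(np.float64) / scale
            tgt = m_ds[start:start + chunk].astype(np.float64)
            cam_terms.append(((cam - tgt) ** 2).mean(axis=(1, 2))
                             if config.cam_loss == "mse"
                             else _dice_per_image(cam, tgt))
    ce = float(np.concatenate(ce_terms).mean())
    cam = float(np.concatenate(cam_terms).mean()) if cam_terms else 0.0
    total = composite_loss(ce, cam, config).total
    return {"ce": ce, "cam": cam, "total": total, "acc": correct / len(x)}


def _dice_per_image(cam: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    eps = 1e-6
    num = 2.0 * (cam * tgt).sum(axis=(1, 2)) + eps
    den = (cam ** 2).sum(axis=(1, 2)) + (tgt ** 2).sum(axis=(1, 2)) + eps
    return 1.0 - num / den
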