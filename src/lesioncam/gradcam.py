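"""Gradient-weighted class activation mapping (Grad-CAM).

For a class score y^c and last-conv feature maps A^k (K maps of u x v), the
channel weights are the globally pooled score gradients

    alpha_k = (1 / uv) * sum_{i,j} d y^c / d A^k_{ij}

and the map is the rectified weighted sum

    L^c = relu( sum_k alpha_k A^k ).

The map lives at feature resolution; :func:`upsample_cam` lifts it to image
resolution (bilinear) for evaluation, and :func:`downsample_mask` brings a
ground-truth mask down to feature resolution for the training loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

__all__ = ["CAMMap", "compute_cam", "cam_from_features", "normalize_cam",
           "upsample_cam", "downsample_mask"]


@dataclass
class CAMMap:
    """A non-negative activation map with its diagnostic channel weights."""

    values: np.ndarray            # (u, v) or (H, W), >= 0
    channel_weights: np.ndarray   # (K,) pooled-gradient weights alpha_k
    target_class: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("CAM values must be a 2-D array")
        if np.any(self.values < 0):
            raise ValueError("CAM values must be non-negative")


def cam_from_features(a: np.ndarray, da: np.ndarray) -> np.ndarray:
    """Raw Grad-CAM maps for a batch: relu(sum_k alpha_k A^k).

    ``a`` and ``da`` have shape (N, K, u, v); returns (N, u, v) and the
    (N, K) alpha array.
    """
    if a.shape != da.shape:
        raise ValueError("feature maps and gradients must share a shape")
    alpha = da.mean(axis=(2, 3))                       # (N, K)
    raw = np.einsum("nk,nkuv->nuv", alpha, a)
    return np.maximum(raw, 0.0), alpha


def compute_cam(model, image: np.ndarray, class_index: int) -> CAMMap:
    """Grad-CAM for a single image in one forward + one backward pass."""
    x = np.asarray(image, dtype=model.params[0].dtype)
    if x.ndim == 3:
        x = x[None]
    if x.shape[0] != 1:
        raise ValueError("compute_cam expects a single image")
    _, a, da = model.score_gradients(x, class_index)
    raw, alpha = cam_from_features(a.astype(np.float64), da.astype(np.float64))
    return CAMMap(values=raw[0], channel_weights=alpha[0], target_class=class_index)


def normalize_cam(cam: CAMMap) -> CAMMap:
    """Divide by the maximum (no-op for an all-zero map)."""
    m = cam.values.max() if cam.values.size else 0.0
    values = cam.values / m if m > 0 else cam.values.copy()
    return CAMMap(values=values, channel_weights=cam.channel_weights,
                  target_class=cam.target_class, normalized=True)


def upsample_cam(cam: CAMMap, shape: tuple[int, int]) -> CAMMap:
    """Bilinear upsampling to ``shape``; refuses to shrink the map."""
    u, v = cam.values.shape
    h, w = shape
    if h < u or w < v:
        raise ValueError("upsample_cam cannot reduce the map size")
    if (h, w) == (u, v):
        values = cam.values.copy()
    else:
        values = zoom(cam.values, (h / u, w / v), order=1, grid_mode=True,
                      mode="nearest")
    values = np.maximum(values, 0.0)
    return CAMMap(values=values, channel_weights=cam.channel_weights,
                  target_class=cam.target_class, normalized=cam.normalized)


def downsample_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Area-mean reduce a binary mask to ``shape``, then threshold at 0.5.

    Used to compare a ground-truth mask with a CAM at feature resolution.
    Requires integer block sizes (image side a multiple of the CAM side).
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    u, v = shape
    if h % u or w % v:
        raise ValueError(f"mask shape {mask.shape} not divisible by {shape}")
    block = mask.astype(np.float64).reshape(u, h // u, v, w // v).mean(axis=(1, 3))
    return (block >= 0.5).astype(np.float64)
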