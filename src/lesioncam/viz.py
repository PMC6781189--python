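"""PNG export of CAM heatmaps and localization overlays.

Colour conventions: heatmaps run blue (low) to red (high); overlays draw
the ground-truth lesion contour in green and the activated region contour
in blue.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.ndimage import binary_erosion

from .gradcam import CAMMap

__all__ = ["save_heatmap", "save_overlay"]


def _contour(mask: np.ndarray) -> np.ndarray:
    m = mask.astype(bool)
    if not m.any():
        return m
    return m & ~binary_erosion(m)


def save_heatmap(cam: CAMMap, path: str | Path) -> Path:
    """Write a CAM as a blue-to-red heatmap PNG."""
    v = cam.values
    vmax = v.max()
    rgba = colormaps["jet"]((v / vmax) if vmax > 0 else v)
    Image.fromarray((rgba[..., :3] * 255).astype(np.uint8)).save(path)
    return Path(path)


def save_overlay(pixels: np.ndarray, truth: np.ndarray | None,
                 activated: np.ndarray | None, path: str | Path) -> Path:
    """Write an RGB frame with truth (green) and activation (blue) contours."""
    img = np.clip(np.asarray(pixels, dtype=np.float64), 0, 1).copy()
    if truth is not None:
        img[_contour(truth)] = (0.0, 1.0, 0.0)
    if activated is not None:
        img[_contour(activated)] = (0.0, 0.3, 1.0)
    Image.fromarray(np.round(img * 255).astype(np.uint8)).save(path)
    return Path(path)
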