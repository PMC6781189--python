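"""Seeded synthetic endoscopy-like cohorts with planted lesions.

The study data are hospital endoscopy images that were never deposited, so
this module is the package's stand-in: patient-grouped RGB frames over a
warm, texture-correlated mucosal background, with a minority of frames
carrying a planted lesion whose ground-truth mask is known exactly.

The class cues mirror the clinical depth cues in spirit: mucosal lesions
(T1a) differ from background by surface texture and a mild colour shift;
submucosal lesions (T1b) add a brighter marginal rim and a stronger colour
shift.  Cues are deliberately subtle — the lesion occupies a minority of
the frame and the classes share texture statistics — so a classifier can
latch onto background shortcuts unless guided toward the lesion.

Everything is a pure function of (seed, parameters).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import binary_erosion, gaussian_filter

CLASSES = ("nonEGC", "T1a", "T1b")

__all__ = ["CLASSES", "LesionParams", "LabeledImage", "SyntheticCohort",
           "default_class_params", "generate_lesion_mask", "render_image",
           "generate_cohort", "write_cohort", "read_cohort"]


@dataclass(frozen=True)
class LesionParams:
    """Geometry and appearance of a planted lesion.

    base_radius_fraction : mean lesion radius as a fraction of the image
        side, in (0, 0.5).
    boundary_irregularity : amplitude of the smooth radial perturbation of
        the lesion boundary (0 = exact ellipse).
    texture_contrast : amplitude of the in-lesion surface roughness, [0, 1].
    rim_strength : brightness of the marginal rim at the lesion boundary,
        [0, 1] — the submucosal (T1b) cue.
    color_shift : amplitude of the reddish colour offset inside the lesion.
    """

    base_radius_fraction: float = 0.18
    boundary_irregularity: float = 0.3
    texture_contrast: float = 0.12
    rim_strength: float = 0.0
    color_shift: float = 0.04
    vignette: float = 0.0

    def validate(self) -> None:
        if not (0.0 < self.base_radius_fraction < 0.5):
            raise ValueError("base_radius_fraction must lie in (0, 0.5)")
        for name in ("boundary_irregularity", "texture_contrast",
                     "rim_strength", "color_shift", "vignette"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


def default_class_params() -> dict[str, LesionParams]:
    """Per-class appearance defaults: texture-only T1a, texture+rim T1b."""
    return {
        "T1a": LesionParams(texture_contrast=0.12, rim_strength=0.0,
                            color_shift=0.04),
        "T1b": LesionParams(texture_contrast=0.15, rim_strength=0.35,
                            color_shift=0.08),
    }


@dataclass
class LabeledImage:
    image_id: str
    patient_id: str
    pixels: np.ndarray                 # (H, W, 3) in [0, 1]
    class_label: str
    lesion_mask: np.ndarray | None = None   # (H, W) bool
    quality_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        has_mask = self.lesion_mask is not None
        if has_mask != (self.class_label != "nonEGC"):
            raise ValueError("lesion_mask must be present iff the class is a lesion class")
        if has_mask:
            if self.lesion_mask.shape != self.pixels.shape[:2]:
                raise ValueError("mask and image shapes differ")
            if not self.lesion_mask.any():
                raise ValueError("lesion mask has no foreground")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    images: list[LabeledImage]
    patients: dict[str, list[str]]
    seed: int
    generation_params: dict

    def __post_init__(self) -> None:
        owners: dict[str, str] = {}
        for pid, ids in self.patients.items():
            for iid in ids:
                if iid in owners:
                    raise ValueError(f"image {iid} assigned to two patients")
                owners[iid] = pid
        for im in self.images:
            if owners.get(im.image_id) != im.patient_id:
                raise ValueError(f"image {im.image_id} not registered to its patient")

    def labels_frame(self) -> pd.DataFrame:
        rows = [{"image_id": im.image_id, "patient_id": im.patient_id,
                 "class": im.class_label,
                 "mask_path": (f"masks/{im.image_id}.png"
                               if im.lesion_mask is not None else "")}
                for im in self.images]
        return pd.DataFrame(rows, columns=["image_id", "patient_id", "class",
                                           "mask_path"])


# ---------------------------------------------------------------------------
# mask geometry

_AREA_LO, _AREA_HI = 0.01, 0.40


def _radial_profile(theta: np.ndarray, rx: float, ry: float,
                    coeffs: np.ndarray, phases: np.ndarray) -> np.ndarray:
    # ellipse polar radius, then a smooth periodic perturbation
    r_e = rx * ry / np.sqrt((ry * np.cos(theta)) ** 2 + (rx * np.sin(theta)) ** 2)
    perturb = np.zeros_like(theta)
    for m, (c, ph) in enumerate(zip(coeffs, phases), start=2):
        perturb += c * np.cos(m * theta + ph)
    return r_e * (1.0 + np.clip(perturb, -0.6, 0.6))


def _fill_mask(side: int, cx: float, cy: float, rx: float, ry: float,
               coeffs: np.ndarray, phases: np.ndarray) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    return r <= _radial_profile(theta, rx, ry, coeffs, phases)


def generate_lesion_mask(image_side: int, params: LesionParams,
                         rng: np.random.Generator) -> np.ndarray:
    """A single connected lesion blob as a boolean (side, side) mask.

    The blob is an ellipse with a smoothed random radial boundary
    perturbation, centred uniformly at random so that it fits in frame;
    its area always lands in [1%, 40%] of the frame (rescaled once if the
    random draw strays outside).
    """
    params.validate()
    if image_side < 16:
        raise ValueError("image_side must be >= 16")
    side = int(image_side)
    rx = params.base_radius_fraction * side
    ry = rx * rng.uniform(0.7, 1.0)
    if rng.random() < 0.5:
        rx, ry = ry, rx
    amp = min(params.boundary_irregularity, 0.6)
    harmonics = 4
    raw = rng.normal(size=harmonics) / np.arange(2, 2 + harmonics)
    norm = np.abs(raw).sum()
    coeffs = (raw / norm * amp * 0.5) if (norm > 0 and amp > 0) else np.zeros(harmonics)
    phases = rng.uniform(0, 2 * np.pi, size=harmonics)
    margin = max(rx, ry) * 1.6 + 1
    margin = min(margin, side / 2 - 1)
    cx = rng.uniform(margin, side - margin)
    cy = rng.uniform(margin, side - margin)

    mask = _fill_mask(side, cx, cy, rx, ry, coeffs, phases)
    frac = mask.mean()
    if not (_AREA_LO <= frac <= _AREA_HI):
        target = np.clip(frac, _AREA_LO * 1.2, _AREA_HI * 0.95)
        scale = np.sqrt(target / max(frac, 1e-9))
        mask = _fill_mask(side, cx, cy, rx * scale, ry * scale, coeffs, phases)
    if not mask.any():   # pathological shrink: fall back to a small disc
        mask = _fill_mask(side, cx, cy, 0.12 * side, 0.12 * side,
                          np.zeros(harmonics), phases)
    return mask


# ---------------------------------------------------------------------------
# rendering

def _correlated_noise(side: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    noise = gaussian_filter(rng.normal(size=(side, side)), sigma)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def render_image(class_label: str, mask: np.ndarray | None,
                 params: LesionParams, rng: np.random.Generator, *,
                 image_side: int | None = None, image_id: str = "img",
                 patient_id: str = "p", benign_patch: bool = False,
                 n_specks: int = 0) -> LabeledImage:
    """Render one frame: warm textured background, plus class-dependent
    perturbations restricted to the mask for lesion classes."""
    params.validate()
    if (mask is not None) != (class_label != "nonEGC"):
        raise ValueError("mask must be provided iff class is a lesion class")
    side = int(mask.shape[0] if mask is not None else (image_side or 128))

    base = np.array([0.58, 0.35, 0.27]) + rng.uniform(-0.04, 0.04)
    img = np.ones((side, side, 3)) * base
    coarse = _correlated_noise(side, side / 16, rng) * 0.06
    fine = rng.normal(scale=0.015, size=(side, side))
    img += (coarse + fine)[:, :, None] * np.array([1.0, 0.9, 0.8])

    # smooth rugal folds: class-independent background relief every frame
    # shows regardless of disease state
    yy, xx = np.mgrid[0:side, 0:side]
    n_folds = int(rng.integers(1, 4))
    for _ in range(n_folds):
        angle = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(1.5, 3.0) * 2 * np.pi / side
        ridge = np.sin((xx * np.cos(angle) + yy * np.sin(angle)) * freq + phase)
        img += (0.04 * ridge ** 2)[:, :, None] * np.array([1.0, 0.85, 0.75])

    # procedure-artifact specks: tiny bright particles in the background,
    # outside any lesion.  The cohort generator plants them preferentially
    # on lesion-class frames, emulating the dataset bias of real exams
    # (cancer endoscopies involve more manipulation), which gives an
    # unguided classifier a background shortcut to latch onto.
    if n_specks > 0:
        forbidden = mask if mask is not None else np.zeros((side, side), bool)
        placed = 0
        attempts = 0
        while placed < n_specks and attempts < 50 * n_specks:
            attempts += 1
            sx, sy = rng.uniform(2, side - 2, size=2)
            if forbidden[int(sy), int(sx)]:
                continue
            sr = rng.uniform(0.8, 1.6)
            spot = np.exp(-(((xx - sx) ** 2 + (yy - sy) ** 2) / (2 * sr * sr)))
            img += (rng.uniform(0.25, 0.40) * spot)[:, :, None]
            placed += 1

    if params.vignette > 0:
        yy, xx = np.mgrid[0:side, 0:side]
        r2 = ((xx - side / 2) ** 2 + (yy - side / 2) ** 2) / (side / 2) ** 2
        img *= (1.0 - params.vignette * r2)[:, :, None]

    if mask is not None:
        m = mask.astype(bool)
        rough = _correlated_noise(side, 1.0, rng) * 0.25 * params.texture_contrast
        shift = params.color_shift * np.array([0.8, -0.5, -0.5])
        img[m] += rough[m, None] + shift
        if params.rim_strength > 0:
            interior = binary_erosion(m, iterations=max(1, side // 48))
            rim = m & ~interior
            img[rim] += 0.3 * params.rim_strength
    elif benign_patch:
        # a smooth benign prominence with no mask: a localization distractor
        yy, xx = np.mgrid[0:side, 0:side]
        cx, cy = rng.uniform(0.25 * side, 0.75 * side, size=2)
        r = rng.uniform(0.10, 0.20) * side
        bump = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * r * r)))
        img += 0.10 * bump[:, :, None]

    np.clip(img, 0.0, 1.0, out=img)
    return LabeledImage(image_id=image_id, patient_id=patient_id, pixels=img,
                        class_label=class_label,
                        lesion_mask=(mask.astype(bool) if mask is not None else None))


# ---------------------------------------------------------------------------
# cohort assembly

def generate_cohort(n_patients: int,
                    class_mix: tuple[float, float, float] = (0.852, 0.078, 0.070),
                    images_per_patient: tuple[int, int] = (2, 6),
                    image_side: int = 128,
                    params: dict[str, LesionParams] | None = None,
                    seed: int = 0,
                    benign_patch_prob: float = 0.3,
                    speck_prob_lesion: float = 0.9,
                    speck_prob_normal: float = 0.05) -> SyntheticCohort:
    """Draw a patient-grouped cohort.

    Each patient draws one class from ``class_mix`` (default mirrors the
    study's heavy non-lesion imbalance) and 2–6 frames of that class;
    frames of one patient share lesion morphology (radius scale, boundary
    irregularity draw) with per-frame viewpoint variation, which is what
    makes patient-level splitting consequential.

    Procedure-artifact specks appear on lesion-class frames with
    probability ``speck_prob_lesion`` and on normal frames with
    ``speck_prob_normal``: a deliberate dataset-bias channel emulating the
    background shortcuts of real exam collections.
    """
    if n_patients < 5:
        raise ValueError("n_patients must be >= 5 so five folds are populated")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("class_mix must be 3 non-negative probabilities summing to 1")
    lo, hi = images_per_patient
    if not (1 <= lo <= hi):
        raise ValueError("images_per_patient must be an increasing range >= 1")
    class_params = dict(default_class_params())
    if params:
        class_params.update(params)

    rng = np.random.default_rng(seed)
    images: list[LabeledImage] = []
    patients: dict[str, list[str]] = {}
    for i in range(n_patients):
        pid = f"P{i:04d}"
        label = CLASSES[rng.choice(3, p=mix)]
        n_img = int(rng.integers(lo, hi + 1))
        if label == "nonEGC":
            p_img = LesionParams()
        else:
            base = class_params[label]
            scale = float(rng.uniform(0.85, 1.2))
            p_img = dataclasses.replace(
                base,
                base_radius_fraction=float(np.clip(
                    base.base_radius_fraction * scale, 0.05, 0.45)),
                boundary_irregularity=float(base.boundary_irregularity
                                            * rng.uniform(0.7, 1.3)))
        ids: list[str] = []
        for j in range(n_img):
            iid = f"{pid}_I{j:02d}"
            speck_p = speck_prob_normal if label == "nonEGC" else speck_prob_lesion
            n_specks = int(rng.integers(2, 6)) if rng.random() < speck_p else 0
            if label == "nonEGC":
                im = render_image(label, None, p_img, rng, image_side=image_side,
                                  image_id=iid, patient_id=pid,
                                  benign_patch=bool(rng.random() < benign_patch_prob),
                                  n_specks=n_specks)
            else:
                mask = generate_lesion_mask(image_side, p_img, rng)
                im = render_image(label, mask, p_img, rng,
                                  image_id=iid, patient_id=pid,
                                  n_specks=n_specks)
            images.append(im)
            ids.append(iid)
        patients[pid] = ids

    gen_params = {
        "n_patients": n_patients,
        "class_mix": list(map(float, mix)),
        "images_per_patient": [int(lo), int(hi)],
        "image_side": int(image_side),
        "benign_patch_prob": float(benign_patch_prob),
        "class_params": {k: dataclasses.asdict(v) for k, v in class_params.items()},
    }
    return SyntheticCohort(images=images, patients=patients, seed=seed,
                           generation_params=gen_params)


# ---------------------------------------------------------------------------
# disk round trip (8-bit PNG images, 0/255 grayscale masks, CSV labels)

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    out = Path(outdir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    for im in cohort.images:
        arr = np.round(im.pixels * 255).astype(np.uint8)
        Image.fromarray(arr).save(out / "images" / f"{im.image_id}.png")
        if im.lesion_mask is not None:
            Image.fromarray((im.lesion_mask * 255).astype(np.uint8), mode="L"
                            ).save(out / "masks" / f"{im.image_id}.png")
    cohort.labels_frame().to_csv(out / "labels.csv", index=False)
    with open(out / "generation.json", "w") as fh:
        json.dump({"seed": cohort.seed, "params": cohort.generation_params},
                  fh, indent=2)
    return out


def read_cohort(indir: str | Path) -> SyntheticCohort:
    ind = Path(indir)
    labels = pd.read_csv(ind / "labels.csv", keep_default_na=False)
    with open(ind / "generation.json") as fh:
        meta = json.load(fh)
    images: list[LabeledImage] = []
    patients: dict[str, list[str]] = {}
    for row in labels.to_dict("records"):
        pixels = np.asarray(Image.open(ind / "images" / f"{row['image_id']}.png"),
                            dtype=np.float64) / 255.0
        mask = None
        if row["mask_path"]:
            mask = np.asarray(Image.open(ind / row["mask_path"])) > 127
        images.append(LabeledImage(image_id=row["image_id"],
                                   patient_id=row["patient_id"],
                                   pixels=pixels, class_label=row["class"],
                                   lesion_mask=mask))
        patients.setdefault(row["patient_id"], []).append(row["image_id"])
    return SyntheticCohort(images=images, patients=patients, seed=meta["seed"],
                           generation_params=meta["params"])
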