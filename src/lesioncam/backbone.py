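"""Classifier backbones exposing class scores, last-conv feature maps and
the gradients of any class score with respect to those feature maps.

Three architectures are provided:

``tiny-test``
    Two conv blocks, for desk-scale unit tests and finite-difference checks.
``vgg-style``
    Stacked 3x3 conv blocks with 2x2 max pooling (downsampling factor 8), a
    small homage to the plain-conv family used for the endoscopy task.
``resnet-style``
    A conv stem followed by identity-skip residual blocks.

Every model ends in global average pooling + a linear classifier, so the
last convolutional activation A^k (K maps of u x v) is the natural hook
point for class activation mapping.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .engine import (Adam, Conv2D, Dense, GlobalAvgPool, Layer, MaxPool2,
                     ReLU, ResidualBlock, Sequential)

ARCHITECTURES = ("tiny-test", "vgg-style", "resnet-style")


@dataclass
class ModelConfig:
    """Architecture hyper-parameters for :func:`build_model`."""

    architecture: str = "vgg-style"
    n_classes: int = 2
    input_side: int = 64
    width: int = 8          # base channel count; doubled per block
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")


@dataclass
class TrainingConfig:
    """Optimisation settings for the two training modes.

    ``loss_mode='plain'`` is the standard cross-entropy objective;
    ``loss_mode='lesion'`` adds the Grad-CAM localization term weighted by
    ``w_cam``.  The study prints neither loss weight; 1.0/1.0 is the neutral
    default.
    """

    loss_mode: str = "plain"
    w_ce: float = 1.0
    w_cam: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 16
    seed: int = 0
    pretrained: bool = False
    cam_loss: str = "mse"   # or "dice"

    def __post_init__(self) -> None:
        if self.loss_mode not in ("plain", "lesion"):
            raise ValueError("loss_mode must be 'plain' or 'lesion'")
        if self.w_ce < 0 or self.w_cam < 0:
            raise ValueError("loss weights must be non-negative")
        effective_cam = self.w_cam if self.loss_mode == "lesion" else 0.0
        if self.w_ce + effective_cam <= 0:
            raise ValueError("at least one loss weight must be positive")
        if self.cam_loss not in ("mse", "dice"):
            raise ValueError("cam_loss must be 'mse' or 'dice'")


class ModelHandle:
    """A convolutional classifier split into a feature extractor and a head.

    The split point is the last convolutional activation: ``features(x)``
    returns A of shape (N, K, u, v), ``head_forward(A)`` the class scores
    y^c, and ``score_gradients`` the per-sample dy^c/dA^k needed for
    Grad-CAM.
    """

    def __init__(self, features: Sequential, head: Sequential, config: ModelConfig,
                 downsampling: int) -> None:
        self.features = features
        self.head = head
        self.config = config
        self.downsampling = downsampling
        self.params = features.params + head.params
        self.grads = features.grads + head.grads

    # -- forward ---------------------------------------------------------
    def feature_maps(self, x: np.ndarray) -> np.ndarray:
        self._check_input(x)
        return self.features.forward(x)

    def head_forward(self, a: np.ndarray) -> np.ndarray:
        return self.head.forward(a)

    def scores(self, x: np.ndarray) -> np.ndarray:
        return self.head_forward(self.feature_maps(x))

    # -- backward --------------------------------------------------------
    def head_backward(self, dscores: np.ndarray, accumulate: bool = True) -> np.ndarray:
        return self.head.backward(dscores, accumulate)

    def backward_from_features(self, da: np.ndarray) -> None:
        self.features.backward(da, accumulate=True)

    def score_gradients(self, x: np.ndarray, class_index: int | np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (scores, A, dA) where dA[n] = d y^{c_n} / d A[n].

        ``class_index`` may be a scalar (same class for the whole batch) or a
        per-sample integer array.  Parameter gradients are not touched.
        """
        a = self.feature_maps(x)
        scores = self.head_forward(a)
        n, n_cls = scores.shape
        idx = np.broadcast_to(np.asarray(class_index), (n,))
        if np.any((idx < 0) | (idx >= n_cls)):
            raise ValueError("class index out of range")
        onehot = np.zeros_like(scores)
        onehot[np.arange(n), idx] = 1.0
        da = self.head_backward(onehot, accumulate=False)
        return scores, a, da

    # -- utilities -------------------------------------------------------
    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    def save(self, path) -> None:
        np.savez(path, *self.params)

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state([data[k] for k in data.files])

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[2] != self.config.input_side or \
                x.shape[3] != self.config.input_side:
            raise ValueError(
                f"expected input (N, C, {self.config.input_side}, "
                f"{self.config.input_side}); got {x.shape}")


def build_model(config: ModelConfig) -> ModelHandle:
    """Construct a seeded classifier for one of the named architectures."""
    rng = np.random.default_rng(config.seed)
    dtype = np.dtype(config.dtype).type
    w = config.width
    layers: list[Layer] = []
    if config.architecture == "tiny-test":
        # conv-relu-pool-conv-relu: A sits after the second ReLU
        downsampling = 2
        layers = [Conv2D(3, w, rng=rng, dtype=dtype), ReLU(), MaxPool2(),
                  Conv2D(w, 2 * w, rng=rng, dtype=dtype), ReLU()]
        features = Sequential(layers)
        head = Sequential([GlobalAvgPool(),
                           Dense(2 * w, config.n_classes, rng=rng, dtype=dtype)])
        c_in = 2 * w
    elif config.architecture == "vgg-style":
        # A sits after the third block's last ReLU; the block's pool moves
        # into the head so the CAM keeps the finer input/4 resolution
        downsampling = 4
        c_in = 3
        for c_out in (w, 2 * w, 4 * w):
            layers += [Conv2D(c_in, c_out, rng=rng, dtype=dtype), ReLU(),
                       Conv2D(c_out, c_out, rng=rng, dtype=dtype), ReLU(),
                       MaxPool2()]
            c_in = c_out
        features = Sequential(layers[:-1])   # stop at last ReLU
        head = Sequential([MaxPool2(), GlobalAvgPool(),
                           Dense(c_in, config.n_classes, rng=rng, dtype=dtype)])
    else:  # resnet-style
        downsampling = 4
        c_in = 3
        blocks: list[Layer] = [Conv2D(3, w, rng=rng, dtype=dtype), ReLU(), MaxPool2()]
        blocks += [ResidualBlock(w, rng=rng, dtype=dtype),
                   Conv2D(w, 2 * w, rng=rng, dtype=dtype), ReLU(), MaxPool2(),
                   ResidualBlock(2 * w, rng=rng, dtype=dtype)]
        features = Sequential(blocks)
        head = Sequential([GlobalAvgPool(),
                           Dense(2 * w, config.n_classes, rng=rng, dtype=dtype)])
        c_in = 2 * w

    required_multiple = {"tiny-test": 2, "vgg-style": 8, "resnet-style": 4}
    mult = required_multiple[config.architecture]
    if config.input_side % mult:
        raise ValueError(
            f"input side {config.input_side} must be a multiple of {mult} "
            f"for {config.architecture}")
    if config.input_side < 8:
        raise ValueError("input side must be >= 8")
    return ModelHandle(features, head, config, downsampling)


def predict(model: ModelHandle, images: np.ndarray) -> np.ndarray:
    """Softmax class probabilities, rows in batch order, each summing to 1."""
    scores = model.scores(np.asarray(images, dtype=model.params[0].dtype))
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def make_optimizer(model: ModelHandle, lr: float) -> Adam:
    return Adam(model.params, model.grads, lr=lr)


def clone_model(model: ModelHandle) -> ModelHandle:
    """A structurally identical model carrying a copy of the weights."""
    m = build_model(copy.deepcopy(model.config))
    m.load_state(model.state())
    return m
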