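"""Minimal deterministic CNN engine with explicit backpropagation.

All layers operate on NCHW float arrays.  Every layer caches what its
backward pass needs during ``forward`` and accumulates parameter gradients
into ``.grads`` during ``backward``.  Determinism: all parameter
initialisation is driven by a ``numpy.random.Generator`` passed in by the
caller; no layer holds hidden random state.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "ResidualBlock",
    "Sequential",
    "Adam",
]


class Layer:
    """Base class: parameterless identity."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gout: np.ndarray, accumulate: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    # xp: padded (N, C, Hp, Wp) -> (N, H, W, C*k*k) with stride 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    windows = windows.transpose(0, 2, 3, 1, 4, 5)
    n, h, w = windows.shape[:3]
    return np.ascontiguousarray(windows).reshape(n, h, w, -1)


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, 'same' zero padding, He init."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, *, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.W = w.astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, k)                          # (N, H, W, C*k*k)
        self._cache = (cols, x.shape)
        wmat = self.W.reshape(self.c_out, -1)          # (cout, C*k*k)
        out = cols @ wmat.T + self.b                   # (N, H, W, cout)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, gout: np.ndarray, accumulate: bool = True) -> np.ndarray:
        cols, xshape = self._cache
        n, _, h, w = gout.shape
        k, p = self.k, self.k // 2
        g = gout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)     # (N*H*W, cout)
        if accumulate:
            self.grads[0] += (g.T @ cols.reshape(-1, cols.shape[-1])).reshape(self.W.shape)
            self.grads[1] += g.sum(axis=0)
        # input gradient via col2im
        wmat = self.W.reshape(self.c_out, -1)
        dcols = (g @ wmat).reshape(n, h, w, xshape[1], k, k)
        dxp = np.zeros((n, xshape[1], h + 2 * p, w + 2 * p), dtype=gout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gout: np.ndarray, accumulate: bool = True) -> np.ndarray:
        return np.where(self._mask, gout, 0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; requires even spatial dimensions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even H, W; got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gout: np.ndarray, accumulate: bool = True) -> np.ndarray:
        n, c, h, w = self._inshape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=gout.dtype)
        np.put_along_axis(dr, self._arg[..., None], gout[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray, accumulate: bool = True) -> np.ndarray:
        n, c, h, w = self._inshape
        return np.broadcast_to(gout[:, :, None, None], self._inshape) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, *, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in)).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gout: np.ndarray, accumulate: bool = True) -> np.ndarray:
        if accumulate:
            self.grads[0] += gout.T @ self._x
            self.grads[1] += gout.sum(axis=0)
        return gout @ self.W


class ResidualBlock(Layer):
    """Two 3x3 convolutions with an identity skip: relu(conv2(relu(conv1(x))) + x)."""

    def __init__(self, c: int, *, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.conv1 = Conv2D(c, c, rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(c, c, rng=rng, dtype=dtype)
        self.params = self.conv1.params + self.conv2.params
        self.grads = self.conv1.grads + self.conv2.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        s = h + x
        self._mask = s > 0
        return np.where(self._mask, s, 0)

    def backward(self, gout: np.ndarray, accumulate: bool = True) -> np.ndarray:
        g = np.where(self._mask, gout, 0)
        gb = self.conv1.backward(
            self.relu1.backward(self.conv2.backward(g, accumulate), accumulate), accumulate)
        return gb + g


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers
        for lay in layers:
            self.params += lay.params
            self.grads += lay.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, gout: np.ndarray, accumulate: bool = True) -> np.ndarray:
        for lay in reversed(self.layers):
            gout = lay.backward(gout, accumulate)
        return gout


class Adam:
    """Adam optimizer over a flat list of parameter/gradient array pairs."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
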