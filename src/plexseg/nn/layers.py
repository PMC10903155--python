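"""Minimal 3-D neural-network layers on NumPy with hand-derived backprop.

Everything operates on float32 tensors in channels-last layout
(N, D, H, W, C).  Each layer caches what its backward pass needs during
``forward`` and returns the input gradient from ``backward`` while
accumulating parameter gradients in ``grads``.

Convolutions use a shift-and-GEMM decomposition: the flattened input is
multiplied once against all kernel taps stacked column-wise
(C, k^3 * C_out), and the k^3 result slabs are accumulated into a spatially
shifted output buffer.  This keeps the arithmetic in a single BLAS call per
layer and replaces im2col gathers with contiguous slice adds, which is what
makes CPU training of the scaled-down models practical.
"""

from __future__ import annotations

import itertools
from typing import Dict, List

import numpy as np


class Layer:
    params: Dict[str, np.ndarray]
    grads: Dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3d(Layer):
    """3-D convolution, stride 1, 'same' zero padding for odd kernels.

    Weights are stored as (k, k, k, C_in, C_out); the GEMM view is
    (C_in, k^3 * C_out).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = (k - 1) // 2
        fan_in = c_in * k ** 3
        # He initialisation: suits the ReLU blocks this layer feeds
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, k, c_in, c_out))
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(c_out, dtype=np.float32)}
        self.grads = {"w": np.zeros_like(self.params["w"]),
                      "b": np.zeros_like(self.params["b"])}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, d, h, w, c = x.shape
        k, p, o = self.k, self.pad, self.c_out
        x2 = x.reshape(-1, c)
        e = k - 1
        acc = np.zeros((n, d + e, h + e, w + e, o), dtype=np.float32)
        # one small GEMM per kernel tap; the (Q, O) product stays cache-hot
        # while it is scattered into the shifted accumulator
        for (i, j, l) in itertools.product(range(k), repeat=3):
            zm = x2 @ self.params["w"][i, j, l]
            acc[:, e - i:e - i + d, e - j:e - j + h, e - l:e - l + w, :] += \
                zm.reshape(n, d, h, w, o)
        y = acc[:, e - p:e - p + d, e - p:e - p + h, e - p:e - p + w, :]
        return np.ascontiguousarray(y) + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, d, h, w, c = x.shape
        k, p, o = self.k, self.pad, self.c_out
        e = k - 1
        dye = np.zeros((n, d + e, h + e, w + e, o), dtype=np.float32)
        dye[:, e - p:e - p + d, e - p:e - p + h, e - p:e - p + w, :] = dy
        x2 = x.reshape(-1, c)
        dx2 = np.zeros((x2.shape[0], c), dtype=np.float32)
        for (i, j, l) in itertools.product(range(k), repeat=3):
            dzm = np.ascontiguousarray(
                dye[:, e - i:e - i + d, e - j:e - j + h, e - l:e - l + w, :]
            ).reshape(-1, o)
            self.grads["w"][i, j, l] += x2.T @ dzm
            dx2 += dzm @ self.params["w"][i, j, l].T
        self.grads["b"] += dy.sum(axis=(0, 1, 2, 3))
        return dx2.reshape(x.shape)


class ConvTranspose3d(Layer):
    """Transposed convolution, kernel 2, stride 2, no padding (2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(2, 2, 2, c_in, c_out))
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(c_out, dtype=np.float32)}
        self.grads = {"w": np.zeros_like(self.params["w"]),
                      "b": np.zeros_like(self.params["b"])}

    def _wmat(self) -> np.ndarray:
        c, o = self.c_in, self.c_out
        return np.ascontiguousarray(
            self.params["w"].reshape(8, c, o).transpose(1, 0, 2).reshape(c, 8 * o))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, d, h, w, c = x.shape
        o = self.c_out
        z = (x.reshape(-1, c) @ self._wmat()).reshape(n, d, h, w, 2, 2, 2, o)
        y = z.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(n, 2 * d, 2 * h, 2 * w, o)
        return np.ascontiguousarray(y) + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, d, h, w, c = x.shape
        o = self.c_out
        dz = dy.reshape(n, d, 2, h, 2, w, 2, o).transpose(0, 1, 3, 5, 2, 4, 6, 7)
        dz2 = np.ascontiguousarray(dz).reshape(-1, 8 * o)
        dwmat = x.reshape(-1, c).T @ dz2
        self.grads["w"] += dwmat.reshape(c, 8, o).transpose(1, 0, 2).reshape(
            self.params["w"].shape)
        self.grads["b"] += dy.sum(axis=(0, 1, 2, 3))
        dx = dz2 @ self._wmat().T
        return dx.reshape(x.shape)


class BatchNorm3d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params = {"gamma": np.ones(c, dtype=np.float32),
                       "beta": np.zeros(c, dtype=np.float32)}
        self.grads = {"gamma": np.zeros(c, dtype=np.float32),
                      "beta": np.zeros(c, dtype=np.float32)}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        ax = (0, 1, 2, 3)
        if self.training:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = ((x - mean) * self._istd).astype(np.float32)
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ax = (0, 1, 2, 3)
        m = dy.size // dy.shape[-1]
        self.grads["gamma"] += (dy * self._xhat).sum(axis=ax)
        self.grads["beta"] += dy.sum(axis=ax)
        dxhat = dy * self.params["gamma"]
        # standard batch-norm gradient through the training statistics
        t1 = dxhat.sum(axis=ax)
        t2 = (dxhat * self._xhat).sum(axis=ax)
        dx = (self._istd / m) * (m * dxhat - t1 - self._xhat * t2)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, np.float32(0.0))


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x).astype(np.float32)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy * (1.0 - self._y ** 2)).astype(np.float32)


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, c = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        x8 = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        x8 = np.ascontiguousarray(x8.transpose(0, 1, 3, 5, 7, 2, 4, 6)).reshape(
            n, d // 2, h // 2, w // 2, c, 8)
        self._arg = x8.argmax(axis=-1)
        self._in_shape = x.shape
        return np.ascontiguousarray(x8.max(axis=-1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._in_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dx8 = np.zeros((n, d2, h2, w2, c, 8), dtype=np.float32)
        np.put_along_axis(dx8, self._arg[..., None], dy[..., None], axis=-1)
        dx = dx8.reshape(n, d2, h2, w2, c, 2, 2, 2).transpose(0, 1, 5, 2, 6, 3, 7, 4)
        return np.ascontiguousarray(dx).reshape(n, d, h, w, c)


class Adam:
    """Adam optimizer over a list of layers' parameter dicts."""

    def __init__(self, layers: List[Layer], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def zero_grad(self) -> None:
        for l in self.layers:
            for k in l.grads:
                l.grads[k][...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)
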