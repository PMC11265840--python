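"""Minimal float32 CNN layers with explicit backprop.

No deep-learning framework is assumed: convolutions run through im2col and
a BLAS matmul, which is fast enough for the desk-scale backbone used in
tests. All layers store their forward cache on the instance, so a layer
object serves one forward/backward pair at a time (sufficient for plain
SGD-style training loops).

Array layout is channels-last ``(batch, height, width, channels)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "ReLU", "MaxPool2", "GlobalAveragePool", "Dense"]


class Layer:
    """Forward/backward pair with a flat list of (param, grad) slots."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, He-initialized."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, rng=None) -> None:
        rng = np.random.default_rng(rng)
        fan_in = kernel * kernel * c_in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # windows: (B, H, W, k, k, C) -> (B*H*W, k*k*C)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        b, h, w, c, _, _ = win.shape
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, k * k * c)
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, _ = x.shape
        cols = self._im2col(x)
        out = cols @ self.w + self.b
        if train:
            self._cols = cols
            self._shape = x.shape
        return out.reshape(b, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, _ = dout.shape
        dflat = dout.reshape(b * h * w, self.c_out).astype(np.float32)
        self.dw[...] = self._cols.T @ dflat
        self.db[...] = dflat.sum(axis=0)
        dcols = dflat @ self.w.T  # (B*H*W, k*k*C)
        k, c = self.kernel, self.c_in
        p = k // 2
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        dcols = dcols.reshape(b, h, w, k, k, c)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, p : p + h, p : p + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        blocks = x.reshape(b, h // 2, 2, w // 2, 2, c)
        out = blocks.max(axis=(2, 4))
        if train:
            self._x_blocks = blocks
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        blocks = self._x_blocks
        # route gradient to the max element; split evenly on exact ties
        mask = blocks == self._out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dx = mask * (dout[:, :, None, :, None, :] / counts)
        b, hh, _, ww, _, c = blocks.shape
        return dx.reshape(b, hh * 2, ww * 2, c).astype(np.float32)


class GlobalAveragePool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(
            dout[:, None, None, :] / (h * w), self._shape
        ).astype(np.float32)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng=None) -> None:
        rng = np.random.default_rng(rng)
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return (dout @ self.w.T).astype(np.float32)
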