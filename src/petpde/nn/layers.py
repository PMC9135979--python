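"""Minimal numpy neural-network layers with hand-written gradients.

Each layer exposes a functional ``forward(x, train) -> (y, cache)`` and a
``backward(dy, cache) -> dx`` that accumulates parameter gradients into
``self.grads``. Caching is functional (one cache object per call) so a layer
with shared weights can be applied several times per forward pass — which is
exactly what the unrolled Euler recurrence needs — and gradients from every
application accumulate correctly.

Arrays are NHWC: (batch, height, width, channels). Channels-last makes each
row of a padded image a contiguous matrix, so convolution runs as batched
matrix products over strided views with no gather/scatter buffers — the
difference between practical and impractical single-core training. The
dtype is configurable; float32 is the training dtype, float64 is used by
the finite-difference gradient checks.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class holding named parameters and their gradient accumulators."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)

    def forward(self, x: np.ndarray, train: bool = True):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2D convolution (cross-correlation), stride 1, zero 'same' padding.

    Implemented as one batched matrix product per stencil offset acting on
    strided views of the padded input, so no im2col gather is materialized.
    The weight matrix is laid out (ksize*ksize*in_ch, out_ch) in (di, dj,
    channel) row order. He-normal initialization; ``zero_init`` zeroes weights and bias, used for
    the final layer so a freshly built response network is exactly the zero
    operator.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        ksize: int,
        rng: np.random.Generator,
        zero_init: bool = False,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        if zero_init:
            W = np.zeros((fan_in, out_ch))
        else:
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        self.params["W"] = W.astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)
        self.zero_grad()

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.ksize // 2
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    def _w9(self) -> np.ndarray:
        k = self.ksize
        return self.params["W"].reshape(k * k, self.in_ch, self.out_ch)

    def forward(self, x: np.ndarray, train: bool = True):
        B, H, W, C = x.shape
        k = self.ksize
        xp = np.ascontiguousarray(self._pad(x))
        W9 = self._w9()
        # one batched matrix product per stencil offset; the padded-input
        # slices are strided views, so nothing is gathered or copied
        y = np.empty((B, H, W, self.out_ch), dtype=x.dtype)
        np.matmul(xp[:, 0:H, 0:W, :], W9[0], out=y)
        if k > 1:
            tmp = np.empty_like(y)
            for idx in range(1, k * k):
                di, dj = divmod(idx, k)
                np.matmul(xp[:, di : di + H, dj : dj + W, :], W9[idx], out=tmp)
                y += tmp
        y += self.params["b"]
        return y, (xp, (B, H, W, C))

    def backward(self, dy: np.ndarray, cache):
        xp, (B, H, W, C) = cache
        k, p = self.ksize, self.ksize // 2
        dy = np.ascontiguousarray(dy)
        W9 = self._w9()
        dW9 = self.grads["W"].reshape(k * k, C, self.out_ch)
        self.grads["b"] += dy.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        tmp = np.empty((B, H, W, C), dtype=dy.dtype)
        for idx in range(k * k):
            di, dj = divmod(idx, k)
            np.matmul(dy, W9[idx].T, out=tmp)
            dxp[:, di : di + H, dj : dj + W, :] += tmp
            xs = xp[:, di : di + H, dj : dj + W, :]
            prod = np.matmul(xs.transpose(0, 1, 3, 2), dy)  # (B, H, C, out)
            dW9[idx] += prod.sum(axis=(0, 1))
        return dxp[:, p : p + H, p : p + W, :] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Running statistics are tracked per ``step`` key: a network whose weights
    are shared across the unrolled time steps sees a different activation
    distribution at every step, so inference uses the statistics of the step
    being evaluated rather than one blend of all of them. The affine
    parameters stay shared.
    """

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.n_ch = n_ch
        self.momentum, self.eps = momentum, eps
        self.dtype = dtype
        self.params["gamma"] = np.ones(n_ch, dtype=dtype)
        self.params["beta"] = np.zeros(n_ch, dtype=dtype)
        self.running_mean: dict[int, np.ndarray] = {}
        self.running_var: dict[int, np.ndarray] = {}
        self.zero_grad()

    def _stats(self, step: int) -> tuple[np.ndarray, np.ndarray]:
        if step not in self.running_mean:
            self.running_mean[step] = np.zeros(self.n_ch, dtype=self.dtype)
            self.running_var[step] = np.ones(self.n_ch, dtype=self.dtype)
        return self.running_mean[step], self.running_var[step]

    def forward(self, x: np.ndarray, train: bool = True, step: int = 0):
        rmean, rvar = self._stats(step)
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean[step] = ((1 - m) * rmean + m * mean).astype(self.dtype)
            self.running_var[step] = ((1 - m) * rvar + m * var).astype(self.dtype)
        else:
            mean, var = rmean, rvar
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * ivar
        y = self.params["gamma"] * xhat + self.params["beta"]
        return y.astype(x.dtype, copy=False), (xhat, ivar, train)

    def backward(self, dy: np.ndarray, cache):
        xhat, ivar, train = cache
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] += dy.sum(axis=(0, 1, 2))
        g = self.params["gamma"]
        if not train:
            return dy * (g * ivar)
        N = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (ivar / N) * (N * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy: np.ndarray, cache):
        return dy * cache


class MaxPool2d(Layer):
    """Non-overlapping max pooling; spatial dims must be divisible by the size."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, train: bool = True):
        s = self.size
        B, H, W, C = x.shape
        win = x.reshape(B, H // s, s, W // s, s, C).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(B, H // s, W // s, s * s, C)
        idx = win.argmax(axis=3)
        y = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        return np.ascontiguousarray(y), (idx, x.shape)

    def backward(self, dy: np.ndarray, cache):
        idx, (B, H, W, C) = cache
        s = self.size
        dwin = np.zeros((B, H // s, W // s, s * s, C), dtype=dy.dtype)
        np.put_along_axis(dwin, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = dwin.reshape(B, H // s, W // s, s, s, C).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(dx.reshape(B, H, W, C))


class UpsampleNearest2d(Layer):
    """Nearest-neighbor up-sampling by an integer factor."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = True):
        f = self.factor
        return np.repeat(np.repeat(x, f, axis=1), f, axis=2), None

    def backward(self, dy: np.ndarray, cache):
        f = self.factor
        B, H, W, C = dy.shape
        return dy.reshape(B, H // f, f, W // f, f, C).sum(axis=(2, 4))


def softplus(x: float) -> float:
    """Numerically stable log(1 + exp(x))."""
    return float(np.logaddexp(0.0, x))


def sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def softplus_inverse(y: float) -> float:
    """Inverse of softplus; y must be > 0."""
    if y <= 0:
        raise ValueError("softplus inverse requires a positive argument")
    return float(y + np.log(-np.expm1(-y)))
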