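"""Minimal CPU neural-network engine (NumPy, manual backprop).

Implements exactly the layer set needed by the image-to-image reconstruction
network and the CNN numerical observer: 2-D convolution (same padding),
2×2 average pooling, 2×2 stride-2 transposed convolution, batch
normalization, leaky ReLU, fully connected layers, the Adam optimizer and a
triangular cyclic learning-rate schedule.  Everything is deterministic given
a seeded ``numpy.random.Generator``, which keeps training runs bit-stable on
one CPU.

Data layout is NCHW.  Each layer caches what its backward pass needs; call
``forward(x, train=...)`` then ``backward(dout)``; parameter gradients
accumulate in ``layer.grads`` aligned with ``layer.params``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ConvTranspose2d", "BatchNorm2d", "LeakyReLU", "AvgPool2d",
           "Linear", "Adam", "cyclic_lr", "sigmoid", "param_count"]

DTYPE = np.float32


class Layer:
    """Base: subclasses fill ``params``/``grads`` (parallel lists of arrays)."""
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k×k convolution, stride 1, zero 'same' padding (odd k)."""

    def __init__(self, in_ch, out_ch, k, rng, dtype=DTYPE):
        super().__init__()
        fan_in = in_ch * k * k
        self.w = (rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(out_ch, dtype)
        self.k = k
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        k = self.k
        p = k // 2
        n, c, h, w_ = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # [N, C, H, W, k, k] -> cols [N*H*W, C*k*k]
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w_, c * k * k)
        wm = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wm.T + self.b
        if train:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(
            out.reshape(n, h, w_, -1).transpose(0, 3, 1, 2)).astype(x.dtype, copy=False)

    def backward(self, dout):
        cols, xshape = self._cache
        n, c, h, w_ = xshape
        k = self.k
        p = k // 2
        co = self.w.shape[0]
        dcols_rhs = dout.transpose(0, 2, 3, 1).reshape(n * h * w_, co)
        self.grads[0][...] = (dcols_rhs.T @ cols).reshape(self.w.shape)
        self.grads[1][...] = dcols_rhs.sum(axis=0)
        dcols = (dcols_rhs @ self.w.reshape(co, -1)).reshape(n, h, w_, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w_ + 2 * p), dout.dtype)
        for u in range(k):
            for v in range(k):
                dxp[:, :, u:u + h, v:v + w_] += dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w_] if p else dxp


class ConvTranspose2d(Layer):
    """2×2 transposed convolution with stride 2 (learned 2× upsampling)."""

    def __init__(self, in_ch, out_ch, rng, dtype=DTYPE):
        super().__init__()
        self.w = (rng.standard_normal((in_ch, out_ch, 2, 2)) * np.sqrt(2.0 / in_ch)).astype(dtype)
        self.b = np.zeros(out_ch, dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        n, c, h, w_ = x.shape
        out6 = np.einsum("nchw,couv->nohuwv", x, self.w, optimize=True)
        out = out6.reshape(n, self.w.shape[1], 2 * h, 2 * w_) + self.b[None, :, None, None]
        if train:
            self._cache = x
        return out

    def backward(self, dout):
        x = self._cache
        n, c, h, w_ = x.shape
        co = self.w.shape[1]
        d6 = dout.reshape(n, co, h, 2, w_, 2)
        self.grads[0][...] = np.einsum("nchw,nohuwv->couv", x, d6, optimize=True)
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dx = np.einsum("nohuwv,couv->nchw", d6, self.w, optimize=True)
        self._cache = None
        return dx


class BatchNorm2d(Layer):
    def __init__(self, ch, momentum=0.1, eps=1e-5, dtype=DTYPE):
        super().__init__()
        self.gamma = np.ones(ch, dtype)
        self.beta = np.zeros(ch, dtype)
        self.running_mean = np.zeros(ch, np.float64)
        self.running_var = np.ones(ch, np.float64)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean.astype(np.float64) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float64) - self.running_var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, invstd = self._cache
        n, c, h, w_ = dout.shape
        m = n * h * w_
        self.grads[0][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (invstd[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        self._cache = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        scale = np.where(x > 0, 1.0, self.slope).astype(x.dtype)
        if train:
            self._cache = scale
        return x * scale

    def backward(self, dout):
        scale = self._cache
        self._cache = None
        return dout * scale


class AvgPool2d(Layer):
    """2×2 average pooling, stride 2."""

    def forward(self, x, train=True):
        n, c, h, w_ = x.shape
        if h % 2 or w_ % 2:
            raise ValueError(f"spatial size {h}x{w_} not divisible by 2")
        if train:
            self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w_ // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        n, c, h, w_ = self._shape
        return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) * 0.25


class Linear(Layer):
    def __init__(self, n_in, n_out, rng, dtype=DTYPE):
        super().__init__()
        self.w = (rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        if train:
            self._cache = x
        return x @ self.w.T + self.b

    def backward(self, dout):
        x = self._cache
        self.grads[0][...] = dout.T @ x
        self.grads[1][...] = dout.sum(axis=0)
        self._cache = None
        return dout @ self.w


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def cyclic_lr(iteration: int, lr_max: float, lr_min: float, period: int) -> float:
    """Triangular cyclic schedule: starts at lr_max, reaches lr_min exactly at
    period/2, returns to lr_max at the end of each period."""
    pos = iteration % period
    half = period / 2.0
    if pos <= half:
        return lr_max - (lr_max - lr_min) * pos / half
    return lr_min + (lr_max - lr_min) * (pos - half) / half


class Adam:
    def __init__(self, params, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.grads = grads
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g.astype(np.float64) ** 2 - v)
            p -= (lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)


def param_count(layers) -> int:
    """Total number of trainable parameter elements across layers."""
    return int(sum(p.size for lay in layers for p in lay.params))
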