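"""Layers used by the segmentation / reconstruction / discriminator networks.

All tensors are channels-first ``(N, C, H, W)`` float arrays.  Convolutions
are lowered to GEMMs via patch extraction; the patch loops run over the
(small) kernel footprint only, never over pixels.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from .core import DEFAULT_DTYPE, Module, Parameter

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype=DEFAULT_DTYPE):
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(dtype)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02, dtype=DEFAULT_DTYPE):
    """Truncated normal init (clipped at +/- 2 std), the ConvNeXt convention.

    The small fixed scale pairs with the pervasive layer normalization:
    activations stay well-conditioned while parameter updates are large
    relative to the weights, which speeds up short training schedules.
    """
    w = rng.normal(0.0, std, size=shape)
    return np.clip(w, -2.0 * std, 2.0 * std).astype(dtype)


class Conv2d(Module):
    """2-D convolution (cross-correlation) with stride/padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, rng: np.random.Generator | None = None,
                 init: str = "trunc", dtype=DEFAULT_DTYPE):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = int(kernel_size)
        self.stride = int(stride)
        self.padding = int(padding)
        shape = (out_channels, in_channels, self.k, self.k)
        fan_in = in_channels * self.k * self.k
        w = trunc_normal(rng, shape, dtype=dtype) if init == "trunc" else             he_normal(rng, shape, fan_in, dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def _im2col(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        n, c, _, _ = xp.shape
        k, s = self.k, self.stride
        cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
        for ki in range(k):
            for kj in range(k):
                cols[:, :, ki, kj] = xp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"Conv2d expects (N,{self.in_channels},H,W), got {x.shape}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        n, c, h, w = xp.shape
        oh = (h - self.k) // self.stride + 1
        ow = (w - self.k) // self.stride + 1
        if self.k == 1 and self.stride == 1:
            # pointwise fast path: pure channel GEMM
            wmat = self.weight.data.reshape(self.out_channels, c)
            y = np.einsum("oc,nchw->nohw", wmat, xp, optimize=True)
            self._cache = ("pw", xp, x.shape)
        else:
            cols = self._im2col(xp, oh, ow)
            y = np.tensordot(cols, self.weight.data, axes=([1, 2, 3], [1, 2, 3]))  # (N,OH,OW,O)
            y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
            self._cache = ("gen", cols if self.training else None, xp.shape, x.shape)
        return y + self.bias.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        kind = self._cache[0]
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        p, s, k = self.padding, self.stride, self.k
        if kind == "pw":
            _, xp, xshape = self._cache
            wmat = self.weight.data.reshape(self.out_channels, -1)
            self.weight.grad += np.einsum("nohw,nchw->oc", dy, xp, optimize=True).reshape(self.weight.data.shape)
            dxp = np.einsum("oc,nohw->nchw", wmat, dy, optimize=True)
        else:
            _, cols, xpshape, xshape = self._cache
            if cols is None:
                raise RuntimeError("backward called on a Conv2d that ran forward in eval mode")
            dyt = dy.transpose(0, 2, 3, 1)  # (N,OH,OW,O)
            self.weight.grad += np.tensordot(dyt, cols, axes=([0, 1, 2], [0, 4, 5]))
            dcols = np.tensordot(dyt, self.weight.data, axes=([3], [0]))  # (N,OH,OW,C,k,k)
            dxp = np.zeros(xpshape, dtype=dy.dtype)
            oh, ow = dy.shape[2], dy.shape[3]
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += \
                        dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class DepthwiseConv2d(Module):
    """Per-channel (depthwise) convolution, stride 1, 'same' padding."""

    def __init__(self, channels: int, kernel_size: int = 7, rng: np.random.Generator | None = None,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.k = int(kernel_size)
        self.padding = self.k // 2
        self.weight = Parameter(trunc_normal(rng, (channels, self.k, self.k), dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"DepthwiseConv2d expects {self.channels} channels, got {x.shape}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, hp, wp = xp.shape
        h, w = x.shape[2], x.shape[3]
        y = np.zeros_like(x)
        wgt = self.weight.data
        for ki in range(self.k):
            for kj in range(self.k):
                y += xp[:, :, ki:ki + h, kj:kj + w] * wgt[:, ki, kj][None, :, None, None]
        self._xp = xp
        return y + self.bias.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        h, w = dy.shape[2], dy.shape[3]
        p = self.padding
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        wgt = self.weight.data
        for ki in range(self.k):
            for kj in range(self.k):
                self.weight.grad[:, ki, kj] += np.einsum(
                    "nchw,nchw->c", dy, xp[:, :, ki:ki + h, kj:kj + w], optimize=True)
                dxp[:, :, ki:ki + h, kj:kj + w] += dy * wgt[:, ki, kj][None, :, None, None]
        return dxp[:, :, p:-p, p:-p] if p else dxp


class LayerNormChannels(Module):
    """Layer normalization across the channel axis at each spatial location.

    This is ConvNeXt's "channels-first" LN: statistics are taken over C for
    every (n, h, w) independently.
    """

    def __init__(self, channels: int, eps: float = 1e-6, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = np.mean(xc * xc, axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += np.einsum("nchw,nchw->c", dy, xhat, optimize=True)
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = np.mean(dxhat * xhat, axis=1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class GELU(Module):
    """Exact (erf-based) Gaussian error linear unit."""

    def __init__(self):
        super().__init__()
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return dy * (cdf + x * pdf)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class HardClip(Module):
    """Clipped-linear unit ``y = clip(x, 0, 1)`` with a straight-through
    gradient at the rails: updates that would move a railed output back
    inside the interval are passed through, all others are blocked.

    Paired with an L1 target this gives per-pixel hinge dynamics: pixels
    already at their target rail go silent instead of dragging shared
    parameters further into saturation (a sigmoid head saturates both
    classes and lets the majority class pull the whole map into collapse).
    """

    def __init__(self):
        super().__init__()
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.clip(x, 0.0, 1.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        inside = (x > 0.0) & (x < 1.0)
        inward = ((x <= 0.0) & (dy < 0.0)) | ((x >= 1.0) & (dy > 0.0))
        return np.where(inside | inward, dy, 0.0)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = Parameter(np.zeros(channels, dtype=dtype), trainable=False)
        self.running_var = Parameter(np.ones(channels, dtype=dtype), trainable=False)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean.data = ((1 - self.momentum) * self.running_mean.data
                                      + self.momentum * mu).astype(x.dtype)
            self.running_var.data = ((1 - self.momentum) * self.running_var.data
                                     + self.momentum * var).astype(x.dtype)
        else:
            mu = self.running_mean.data
            var = self.running_var.data
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += np.einsum("nchw,nchw->c", dy, xhat, optimize=True)
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        if not self.training:
            return dxhat * inv[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return inv[None, :, None, None] / n * (n * dxhat - s1 - xhat * s2)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None,
                 init: str = "trunc", dtype=DEFAULT_DTYPE):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        shape = (out_features, in_features)
        w = trunc_normal(rng, shape, dtype=dtype) if init == "trunc" else             he_normal(rng, shape, in_features, dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class Flatten(Module):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


def _bilinear_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-interpolation matrix for bilinear resize (half-pixel centers)."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        w1 = src - i0
        a[i, i0] += 1.0 - w1
        a[i, i1] += w1
    return a


class UpsampleBilinear(Module):
    """Integer-factor bilinear upsampling (separable interpolation matrices)."""

    def __init__(self, scale: int, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.scale = int(scale)
        self.dtype = dtype
        self._mats: dict[tuple[int, int], np.ndarray] = {}
        self._in_shape = None

    def _mat(self, n_in: int) -> np.ndarray:
        key = (n_in, self.scale)
        if key not in self._mats:
            self._mats[key] = _bilinear_matrix(n_in * self.scale, n_in, self.dtype)
        return self._mats[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        ah = self._mat(x.shape[2])
        aw = self._mat(x.shape[3])
        y = np.einsum("ih,nchw->nciw", ah, x, optimize=True)
        return np.einsum("jw,nciw->ncij", aw, y, optimize=True)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ah = self._mat(self._in_shape[2])
        aw = self._mat(self._in_shape[3])
        t = np.einsum("jw,ncij->nciw", aw, dy, optimize=True)
        return np.einsum("ih,nciw->nchw", ah, t, optimize=True)
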