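"""Layers with explicit forward/backward.  Single-sample, channels-first.

Same-padding convolutions require odd kernels (1 or 3 per axis), which makes
the input gradient an exact flipped-kernel convolution.  Down/upsampling use
kernel-2 stride-2 (per-axis factors of 1 or 2), implemented by axis
reshaping + einsum so no scatter loops are needed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    train_mode = True

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self):
        return []


def _pad_same(x: np.ndarray, kernel) -> np.ndarray:
    pads = [(0, 0)] + [(kk // 2, kk // 2) for kk in kernel]
    return np.pad(x, pads)


def _conv_same_padded(xp: np.ndarray, w: np.ndarray, out_shape) -> np.ndarray:
    """Correlation of pre-padded ``xp`` with ``w`` by shift-and-matmul.

    Accumulating one (Co, Ci) x (Ci, N) matmul per kernel offset avoids the
    large strided im2col copy, which dominates runtime otherwise.
    """
    co, ci, k0, k1, k2 = w.shape
    d, h, ww = out_shape
    n = d * h * ww
    y = np.zeros((co, n), dtype=np.float32)
    for i in range(k0):
        for j in range(k1):
            for l in range(k2):
                xs = xp[:, i : i + d, j : j + h, l : l + ww].reshape(ci, n)
                y += w[:, :, i, j, l] @ xs
    return y.reshape(co, d, h, ww)


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded correlation. x (Ci, D, H, W); w (Co, Ci, k0, k1, k2), k odd."""
    return _conv_same_padded(_pad_same(x, w.shape[2:]), w, x.shape[1:])


class Conv3dSame(Layer):
    """3D convolution, stride 1, same padding, odd kernel (e.g. (3,3,3) or (1,3,3))."""

    def __init__(self, in_c: int, out_c: int, kernel=(3, 3, 3), rng=None, bias: bool = True):
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("same-padded conv needs odd kernels")
        rng = rng or np.random.default_rng(0)
        fan_in = in_c * int(np.prod(kernel))
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_c, in_c, *kernel)))
        self.b = Param(np.zeros(out_c)) if bias else None
        self.kernel = tuple(kernel)
        self._x = None

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._xp = _pad_same(x, self.kernel)
        self._shape = x.shape[1:]
        y = _conv_same_padded(self._xp, self.w.value, self._shape)
        if self.b is not None:
            y += self.b.value[:, None, None, None]
        return y

    def backward(self, g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        co = g.shape[0]
        d, h, ww = self._shape
        n = d * h * ww
        gm = g.reshape(co, n)
        ci = self.w.value.shape[1]
        k0, k1, k2 = self.kernel
        for i in range(k0):
            for j in range(k1):
                for l in range(k2):
                    xs = self._xp[:, i : i + d, j : j + h, l : l + ww].reshape(ci, n)
                    self.w.grad[:, :, i, j, l] += gm @ xs.T
        if self.b is not None:
            self.b.grad += gm.sum(axis=1)
        # input gradient = same-conv of g with channel-swapped, spatially flipped kernel
        wt = np.ascontiguousarray(
            self.w.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        self._xp = None
        return _conv_same(g, wt)

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class ConvDown(Layer):
    """Strided-convolution downsampling: kernel = stride = ``factors`` (1 or 2 per axis)."""

    def __init__(self, in_c: int, out_c: int, factors=(2, 2, 2), rng=None):
        if any(f not in (1, 2) for f in factors):
            raise ValueError("factors must be 1 or 2 per axis")
        rng = rng or np.random.default_rng(0)
        fan_in = in_c * int(np.prod(factors))
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_c, in_c, *factors)))
        self.b = Param(np.zeros(out_c))
        self.factors = tuple(factors)
        self._xr = None

    def _reshape(self, x):
        c, d, h, w = x.shape
        f = self.factors
        if d % f[0] or h % f[1] or w % f[2]:
            raise ValueError(f"shape {x.shape[1:]} not divisible by factors {f}")
        return x.reshape(c, d // f[0], f[0], h // f[1], f[1], w // f[2], f[2])

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        xr = self._reshape(x)
        self._xr = xr
        y = np.einsum("cdahbwe,ocabe->odhw", xr, self.w.value, optimize=True)
        return y + self.b.value[:, None, None, None]

    def backward(self, g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        self.w.grad += np.einsum("odhw,cdahbwe->ocabe", g, self._xr, optimize=True)
        self.b.grad += g.sum(axis=(1, 2, 3))
        gx = np.einsum("odhw,ocabe->cdahbwe", g, self.w.value, optimize=True)
        c = gx.shape[0]
        self._xr = None
        return np.ascontiguousarray(gx).reshape(
            c,
            gx.shape[1] * gx.shape[2],
            gx.shape[3] * gx.shape[4],
            gx.shape[5] * gx.shape[6],
        )

    def params(self):
        return [self.w, self.b]


class ConvUp(Layer):
    """Transpose-convolution upsampling, kernel = stride = ``factors``."""

    def __init__(self, in_c: int, out_c: int, factors=(2, 2, 2), rng=None):
        if any(f not in (1, 2) for f in factors):
            raise ValueError("factors must be 1 or 2 per axis")
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / in_c), (in_c, out_c, *factors)))
        self.b = Param(np.zeros(out_c))
        self.factors = tuple(factors)
        self._x = None

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._x = x
        yr = np.einsum("cdhw,coabe->odahbwe", x, self.w.value, optimize=True)
        o = yr.shape[0]
        y = np.ascontiguousarray(yr).reshape(
            o,
            yr.shape[1] * yr.shape[2],
            yr.shape[3] * yr.shape[4],
            yr.shape[5] * yr.shape[6],
        )
        return y + self.b.value[:, None, None, None]

    def backward(self, g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        o, d, h, w = g.shape
        f = self.factors
        gr = g.reshape(o, d // f[0], f[0], h // f[1], f[1], w // f[2], f[2])
        self.w.grad += np.einsum("cdhw,odahbwe->coabe", self._x, gr, optimize=True)
        self.b.grad += g.sum(axis=(1, 2, 3))
        self._x = None
        return np.einsum("odahbwe,coabe->cdhw", gr, self.w.value, optimize=True)

    def params(self):
        return [self.w, self.b]


class GroupNorm(Layer):
    """Group normalization over (channels-in-group x all spatial positions)."""

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.channels, self.groups, self.eps = channels, groups, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self._cache = None

    def forward(self, x):
        x = np.asarray(x, dtype=np.float32)
        c = x.shape[0]
        xg = x.reshape(self.groups, -1)
        mu = xg.mean(axis=1, keepdims=True)
        var = xg.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(x.shape)
        self._cache = (xhat, inv)
        return self.gamma.value[:, None, None, None] * xhat + self.beta.value[:, None, None, None]

    def backward(self, g):
        xhat, inv = self._cache
        self._cache = None
        g = np.asarray(g, dtype=np.float32)
        self.gamma.grad += (g * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += g.sum(axis=(1, 2, 3))
        dxhat = (g * self.gamma.value[:, None, None, None]).reshape(self.groups, -1)
        xh = xhat.reshape(self.groups, -1)
        m = dxhat.shape[1]
        gx = inv * (dxhat - dxhat.mean(axis=1, keepdims=True) - xh * (dxhat * xh).mean(axis=1, keepdims=True))
        return gx.reshape(g.shape)

    def params(self):
        return [self.gamma, self.beta]


class BatchNorm(GroupNorm):
    """Per-channel normalization.

    With single-sample training (batch size 1) batch statistics reduce to
    per-channel spatial statistics, i.e. group norm with one channel per
    group; kept as a distinct class so architecture audits can tell the two
    normalizations apart.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__(channels, groups=channels, eps=eps)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, g):
        return np.where(self._mask, g, 0.0).astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(np.float32)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g).astype(np.float32)


class ChannelSoftmax(Layer):
    """Softmax across the channel axis (per-voxel class competition)."""

    def forward(self, x):
        e = np.exp(x - x.max(axis=0, keepdims=True))
        self._y = (e / e.sum(axis=0, keepdims=True)).astype(np.float32)
        return self._y

    def backward(self, g):
        y = self._y
        return (y * (g - (g * y).sum(axis=0, keepdims=True))).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        self._y = y.astype(np.float32)
        return self._y

    def backward(self, g):
        return (g * self._y * (1.0 - self._y)).astype(np.float32)


class MaxPool(Layer):
    """Max pooling with per-axis factors (1 or 2); e.g. (1, 2, 2) pools in-plane only."""

    def __init__(self, factors=(1, 2, 2)):
        self.factors = tuple(factors)

    def forward(self, x):
        c, d, h, w = x.shape
        f = self.factors
        if d % f[0] or h % f[1] or w % f[2]:
            raise ValueError(f"shape {x.shape[1:]} not divisible by pool factors {f}")
        xr = x.reshape(c, d // f[0], f[0], h // f[1], f[1], w // f[2], f[2])
        xr = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
            c, d // f[0], h // f[1], w // f[2], -1
        )
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, g):
        c, d, h, w = self._shape
        f = self.factors
        n = int(np.prod(f))
        gr = np.zeros((c, d // f[0], h // f[1], w // f[2], n), dtype=np.float32)
        np.put_along_axis(gr, self._arg[..., None], g[..., None].astype(np.float32), axis=-1)
        gr = gr.reshape(c, d // f[0], h // f[1], w // f[2], f[0], f[1], f[2])
        gr = gr.transpose(0, 1, 4, 2, 5, 3, 6)
        return np.ascontiguousarray(gr).reshape(c, d, h, w)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer
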