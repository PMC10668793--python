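"""Convolution, normalization, activation and pooling layers.

Convolutions are evaluated by unrolling the kernel footprint into a
``(N, C, k*k, Ho, Wo)`` view assembled from strided slices and contracting
with BLAS; the backward pass redistributes gradients with the mirrored
slice loop.  Kernels here are at most 7x7, so the k*k Python loop is cheap
relative to the matmuls it feeds.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:                                   # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(fn):
            return fn
        return wrap


@_njit(cache=True)
def _dw_forward_kernel(xp, w, s, k, ho, wo, y):
    # kernel taps outermost, contiguous row sweeps innermost (SIMD-friendly)
    n, c = xp.shape[0], xp.shape[1]
    for b in range(n):
        for ch in range(c):
            for oh in range(ho):
                for ow in range(wo):
                    y[b, ch, oh, ow] = 0.0
            for i in range(k):
                for j in range(k):
                    wv = w[ch, i * k + j]
                    for oh in range(ho):
                        hi = oh * s + i
                        for ow in range(wo):
                            y[b, ch, oh, ow] += xp[b, ch, hi, ow * s + j] * wv


@_njit(cache=True)
def _dw_backward_kernel(xp, w, dy, s, k, ho, wo, dxp, dw):
    n, c = xp.shape[0], xp.shape[1]
    for b in range(n):
        for ch in range(c):
            for i in range(k):
                for j in range(k):
                    wv = w[ch, i * k + j]
                    acc = 0.0
                    for oh in range(ho):
                        hi = oh * s + i
                        for ow in range(wo):
                            g = dy[b, ch, oh, ow]
                            wj = ow * s + j
                            dxp[b, ch, hi, wj] += g * wv
                            acc += g * xp[b, ch, hi, wj]
                    dw[ch, i * k + j] += acc

__all__ = ["Conv2d", "BatchNorm2d", "ReLU6", "Sigmoid", "MaxPool2d", "Identity"]


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _out_size(size, k, s, p):
    return (size + 2 * p - k) // s + 1


def _unfold(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, k*k, ho, wo) by slicing per kernel offset."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k * k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i : i + (ho - 1) * s + 1 : s,
                                       j : j + (wo - 1) * s + 1 : s]
    return cols


def _fold_add(dxp: np.ndarray, dcols: np.ndarray, k: int, s: int, ho: int, wo: int):
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + (ho - 1) * s + 1 : s,
                j : j + (wo - 1) * s + 1 : s] += dcols[:, :, i * k + j]


class Conv2d(Module):
    """2D convolution with optional grouping (``groups == in_channels`` is
    the depthwise case and takes a cheaper elementwise path)."""

    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError("channels must be divisible by groups")
        self.cin, self.cout, self.k = cin, cout, int(k)
        self.stride, self.padding, self.groups = int(stride), int(padding), groups
        rng = rng or np.random.default_rng()
        fan_in = (cin // groups) * self.k * self.k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(cout, cin // groups, self.k, self.k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.padding
        ho, wo = _out_size(h, k, s, p), _out_size(w, k, s, p)
        self._shape = (n, c, h, w, ho, wo)
        if k == 1 and s == 1 and self.groups == 1:      # pointwise: pure BLAS
            self._cols = x.reshape(n, c, h * w)
            wmat = self.weight.data.reshape(self.cout, c)
            y = np.matmul(wmat[None], self._cols).reshape(n, self.cout, h, w)
            if self.bias is not None:
                y += self.bias.data[None, :, None, None]
            return np.ascontiguousarray(y, dtype=np.float32)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        if self.groups == self.cin == self.cout:        # depthwise
            xp = np.ascontiguousarray(xp, dtype=np.float32)
            self._xp = xp
            wflat = np.ascontiguousarray(
                self.weight.data.reshape(self.cout, k * k))
            y = np.empty((n, c, ho, wo), dtype=np.float32)
            if _HAVE_NUMBA:
                _dw_forward_kernel(xp, wflat, s, k, ho, wo, y)
            else:                                       # pragma: no cover
                y[...] = 0.0
                for i in range(k):
                    for j in range(k):
                        y += xp[:, :, i : i + (ho - 1) * s + 1 : s,
                                j : j + (wo - 1) * s + 1 : s] \
                             * wflat[:, i * k + j][None, :, None, None]
        elif self.groups == 1:
            cols = _unfold(xp, k, s, ho, wo).reshape(n, c * k * k, ho * wo)
            self._cols = cols
            wmat = self.weight.data.reshape(self.cout, c * k * k)
            y = np.matmul(wmat[None], cols).reshape(n, self.cout, ho, wo)
        else:
            g = self.groups
            cg, og = self.cin // g, self.cout // g
            cols = _unfold(xp, k, s, ho, wo).reshape(n, g, cg * k * k, ho * wo)
            self._cols = cols
            wmat = self.weight.data.reshape(g, og, cg * k * k)
            y = np.einsum("gok,ngkl->ngol", wmat, cols,
                          optimize=True).reshape(n, self.cout, ho, wo)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, dy):
        n, c, h, w, ho, wo = self._shape
        k, s, p = self.k, self.stride, self.padding
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if k == 1 and s == 1 and self.groups == 1:
            cols = self._cols                           # (N, C, H*W)
            dyl = dy.reshape(n, self.cout, h * w)
            self.weight.grad += np.einsum(
                "nol,ncl->oc", dyl, cols, optimize=True
            ).reshape(self.weight.data.shape)
            wmat = self.weight.data.reshape(self.cout, c)
            dx = np.matmul(wmat.T[None], dyl).reshape(n, c, h, w)
            self._cols = None
            return np.ascontiguousarray(dx, dtype=np.float32)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        if self.groups == self.cin == self.cout:
            xp = self._xp
            wflat = np.ascontiguousarray(
                self.weight.data.reshape(self.cout, k * k))
            dw = np.zeros((self.cout, k * k), dtype=np.float32)
            dy32 = np.ascontiguousarray(dy, dtype=np.float32)
            if _HAVE_NUMBA:
                _dw_backward_kernel(xp, wflat, dy32, s, k, ho, wo, dxp, dw)
            else:                                       # pragma: no cover
                for i in range(k):
                    for j in range(k):
                        sl = (slice(None), slice(None),
                              slice(i, i + (ho - 1) * s + 1, s),
                              slice(j, j + (wo - 1) * s + 1, s))
                        dw[:, i * k + j] = (xp[sl] * dy32).sum(axis=(0, 2, 3))
                        dxp[sl] += dy32 * wflat[:, i * k + j][None, :, None, None]
            self.weight.grad += dw.reshape(self.weight.data.shape)
            self._xp = None
        elif self.groups == 1:
            cols = self._cols                           # (N, c*k*k, L)
            dyl = dy.reshape(n, self.cout, ho * wo)
            self.weight.grad += np.einsum(
                "nol,nkl->ok", dyl, cols, optimize=True
            ).reshape(self.weight.data.shape)
            wmat = self.weight.data.reshape(self.cout, c * k * k)
            dcols = np.matmul(wmat.T[None], dyl).reshape(n, c, k * k, ho, wo)
            _fold_add(dxp, dcols, k, s, ho, wo)
            self._cols = None
        else:
            g = self.groups
            cg, og = self.cin // g, self.cout // g
            cols = self._cols                           # (N,g,cg*k*k,L)
            dyl = dy.reshape(n, g, og, ho * wo)
            self.weight.grad += np.einsum(
                "ngol,ngkl->gok", dyl, cols, optimize=True
            ).reshape(self.weight.data.shape)
            wmat = self.weight.data.reshape(g, og, cg * k * k)
            dcols = np.einsum("gok,ngol->ngkl", wmat, dyl,
                              optimize=True).reshape(n, c, k * k, ho, wo)
            _fold_add(dxp, dcols, k, s, ho, wo)
            self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean += m * (mean - self.running_mean)
            self.running_var += m * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None]).astype(np.float32)

    def backward(self, dy):
        xhat, inv = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not self.training:
            return (dy * g * inv[None, :, None, None]).astype(np.float32)
        nhw = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return (dx * inv[None, :, None, None]).astype(np.float32)


class ReLU6(Module):
    def forward(self, x):
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class Sigmoid(Module):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        dx = dy * self._y * (1.0 - self._y)
        self._y = None
        return dx


class Identity(Module):
    def forward(self, x):
        return x

    def backward(self, dy):
        return dy


class MaxPool2d(Module):
    """Max pooling; SPP uses stride 1 with ``padding = k // 2``.

    The argmax (as a kernel-offset index) is tracked with a running
    comparison so the window stack is never materialized.
    """

    def __init__(self, k, stride=1, padding=None):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.k = int(k)
        self.stride = int(stride)
        self.padding = self.k // 2 if padding is None else int(padding)

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.padding
        ho, wo = _out_size(h, k, s, p), _out_size(w, k, s, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
        # separable max with argmax tracking: width pass then height pass
        bw = np.full((n, c, h + 2 * p, wo), -np.inf, dtype=np.float32)
        argw = np.zeros((n, c, h + 2 * p, wo), dtype=np.int32)
        for j in range(k):
            sl = xp[:, :, :, j : j + (wo - 1) * s + 1 : s]
            m = sl > bw
            bw = np.where(m, sl, bw)
            argw[m] = j
        best = np.full((n, c, ho, wo), -np.inf, dtype=np.float32)
        argh = np.zeros((n, c, ho, wo), dtype=np.int32)
        for i in range(k):
            sl = bw[:, :, i : i + (ho - 1) * s + 1 : s]
            m = sl > best
            best = np.where(m, sl, best)
            argh[m] = i
        self._cache = (argw, argh, (n, c, h, w, ho, wo))
        return best

    def backward(self, dy):
        argw, argh, (n, c, h, w, ho, wo) = self._cache
        self._cache = None
        k, s, p = self.k, self.stride, self.padding
        hp, wp = h + 2 * p, w + 2 * p
        # absolute source row/col in the padded frame for each output cell
        rows = argh + np.arange(0, ho * s, s)[None, None, :, None]
        cols_in_bw = rows * wo + np.arange(wo)[None, None, None, :]
        argw_sel = np.take_along_axis(
            argw.reshape(n, c, -1), cols_in_bw.reshape(n, c, -1), axis=2
        ).reshape(n, c, ho, wo)
        cols = argw_sel + np.arange(0, wo * s, s)[None, None, None, :]
        dxp = np.zeros((n, c, hp * wp), dtype=np.float32)
        flat = (rows * wp + cols).reshape(n, c, -1)
        np.add.at(dxp, (np.arange(n)[:, None, None], np.arange(c)[None, :, None], flat),
                  dy.reshape(n, c, -1))
        dxp = dxp.reshape(n, c, hp, wp)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp
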