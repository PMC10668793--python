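"""Building blocks of the SH-SSD detector.

The Triple Attention (TA) block gates the input with three sigmoid masks
obtained by pooling over the channel, height and width axes respectively;
each branch compresses the pooled pair (max, mean) with a single bias-free
7x7 convolution followed by batch norm, so a TA block costs 300 trainable
scalars regardless of the channel count.  TAneck is the MobileNetV3
inverted bottleneck with the squeeze-excitation block replaced by TA.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm2d, Conv2d, MaxPool2d, Module, ReLU6, Sequential, Sigmoid

__all__ = ["CBR", "DWCBR", "TripleAttention", "SqueezeExcite", "TANeck", "SPP"]


class CBR(Sequential):
    """Convolution + BatchNorm + ReLU6."""

    def __init__(self, cin, cout, k, stride=1, rng=None):
        super().__init__(
            Conv2d(cin, cout, k, stride=stride, padding=k // 2, bias=False, rng=rng),
            BatchNorm2d(cout),
            ReLU6(),
        )


class DWCBR(Sequential):
    """Depthwise convolution + BatchNorm + ReLU6 (groups == channels)."""

    def __init__(self, c, k, stride=1, rng=None):
        super().__init__(
            Conv2d(c, c, k, stride=stride, padding=k // 2, groups=c, bias=False, rng=rng),
            BatchNorm2d(c),
            ReLU6(),
        )


class _TABranch(Module):
    """One attention branch: pool an axis to (max, mean), 7x7 conv -> BN ->
    sigmoid, multiply back.  ``perm`` moves the pooled axis to the channel
    position; all three perms used are involutions.

    The attention conv pads by edge replication so that a constant input
    yields an exactly constant pre-BN map (hence a uniform 0.5 gate)."""

    PAD = 3

    def __init__(self, perm, rng=None):
        super().__init__()
        self.perm = perm
        self.conv = Conv2d(2, 1, 7, padding=0, bias=False, rng=rng)
        self.bn = BatchNorm2d(1)
        self.sig = Sigmoid()

    def _pad(self, z):
        p = self.PAD
        return np.pad(z, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")

    def _unpad_grad(self, dzp):
        p = self.PAD
        dz = dzp[:, :, p:-p, p:-p].copy()
        dz[:, :, 0, :] += dzp[:, :, :p, p:-p].sum(axis=2)
        dz[:, :, -1, :] += dzp[:, :, -p:, p:-p].sum(axis=2)
        dz[:, :, :, 0] += dzp[:, :, p:-p, :p].sum(axis=3)
        dz[:, :, :, -1] += dzp[:, :, p:-p, -p:].sum(axis=3)
        dz[:, :, 0, 0] += dzp[:, :, :p, :p].sum(axis=(2, 3))
        dz[:, :, 0, -1] += dzp[:, :, :p, -p:].sum(axis=(2, 3))
        dz[:, :, -1, 0] += dzp[:, :, -p:, :p].sum(axis=(2, 3))
        dz[:, :, -1, -1] += dzp[:, :, -p:, -p:].sum(axis=(2, 3))
        return dz

    def forward(self, x):
        xb = np.ascontiguousarray(x.transpose(self.perm))
        self._arg = np.argmax(xb, axis=1)
        z = np.stack([np.take_along_axis(xb, self._arg[:, None], axis=1)[:, 0],
                      xb.mean(axis=1)], axis=1)
        g = self.sig(self.bn(self.conv(self._pad(z))))
        self._xb, self._g = xb, g
        return (xb * g).transpose(self.perm)

    def backward(self, dy):
        xb, g = self._xb, self._g
        dyb = dy.transpose(self.perm)
        dg = (dyb * xb).sum(axis=1, keepdims=True)
        dxb = dyb * g
        dzp = self.conv.backward(self.bn.backward(self.sig.backward(dg)))
        dz = self._unpad_grad(dzp)
        dmax, dmean = dz[:, 0], dz[:, 1]
        scatter = np.zeros_like(xb)
        np.put_along_axis(scatter, self._arg[:, None], dmax[:, None], axis=1)
        dxb += scatter
        dxb += dmean[:, None] / xb.shape[1]
        self._xb = self._g = self._arg = None
        return np.ascontiguousarray(dxb.transpose(self.perm))


class TripleAttention(Module):
    """Three-branch attention over (channel, height, width); branch outputs
    are merged by averaging.  Shape-preserving for any input."""

    def __init__(self, rng=None):
        super().__init__()
        self.branches = [
            _TABranch((0, 1, 2, 3), rng),   # pool over channels -> spatial gate
            _TABranch((0, 2, 1, 3), rng),   # pool over height   -> (C, W) gate
            _TABranch((0, 3, 2, 1), rng),   # pool over width    -> (H, C) gate
        ]

    def forward(self, x):
        return sum(b(x) for b in self.branches) / 3.0

    def backward(self, dy):
        third = dy / 3.0
        return sum(b.backward(third) for b in self.branches)


class SqueezeExcite(Module):
    """SENet-style channel gate (used by the plain-SE backbone variant that
    the parameter audit compares against): global average pool, reduce by
    ``reduction`` (hidden width floored to a multiple of 8, minimum 8),
    expand back, sigmoid scale."""

    def __init__(self, c, reduction=16, rng=None):
        super().__init__()
        hidden = max((c // reduction) // 8 * 8, 8)
        self.fc1 = Conv2d(c, hidden, 1, bias=True, rng=rng)
        self.act = ReLU6()
        self.fc2 = Conv2d(hidden, c, 1, bias=True, rng=rng)
        self.sig = Sigmoid()

    def forward(self, x):
        self._x = x
        s = x.mean(axis=(2, 3), keepdims=True)
        self._g = self.sig(self.fc2(self.act(self.fc1(s))))
        return x * self._g

    def backward(self, dy):
        x, g = self._x, self._g
        dg = (dy * x).sum(axis=(2, 3), keepdims=True)
        ds = self.fc1.backward(self.act.backward(self.fc2.backward(self.sig.backward(dg))))
        dx = dy * g + ds / (x.shape[2] * x.shape[3])
        self._x = self._g = None
        return dx


class TANeck(Module):
    """Inverted bottleneck: 1x1 expand (skipped when ``exp == cin``),
    depthwise k x k with stride, optional attention, 1x1 CBR projection,
    residual when the input and output shapes agree.

    ``attention`` selects the gate: "ta" (after the depthwise stage, per the
    TA design) or "se" (on the projected output, the plain-SE variant)."""

    def __init__(self, cin, exp, out, k, stride=1, use_attn=True, use_res=False,
                 attention="ta", rng=None):
        super().__init__()
        if use_res and (stride != 1 or cin != out):
            raise ValueError(
                f"residual requires stride 1 and cin == cout, got "
                f"stride={stride}, cin={cin}, cout={out}")
        self.use_res = use_res
        self.expand = CBR(cin, exp, 1, rng=rng) if exp != cin else None
        self.dw = DWCBR(exp, k, stride=stride, rng=rng)
        self.attention_kind = attention if use_attn else None
        if not use_attn:
            self.attn = None
        elif attention == "ta":
            self.attn = TripleAttention(rng)
        elif attention == "se":
            self.attn = SqueezeExcite(out, rng=rng)
        else:
            raise ValueError(f"unknown attention {attention!r}")
        self.project = CBR(exp, out, 1, rng=rng)

    def forward(self, x):
        y = self.expand(x) if self.expand is not None else x
        y = self.dw(y)
        if self.attention_kind == "ta":
            y = self.attn(y)
        y = self.project(y)
        if self.attention_kind == "se":
            y = self.attn(y)
        return y + x if self.use_res else y

    def backward(self, dy):
        d = dy
        if self.attention_kind == "se":
            d = self.attn.backward(d)
        d = self.project.backward(d)
        if self.attention_kind == "ta":
            d = self.attn.backward(d)
        d = self.dw.backward(d)
        if self.expand is not None:
            d = self.expand.backward(d)
        return d + dy if self.use_res else d


class SPP(Module):
    """Spatial pyramid pooling: concatenate the input with three stride-1
    max-pooled copies, quadrupling the channel count."""

    def __init__(self, kernels=(5, 9, 13)):
        super().__init__()
        if any(k % 2 == 0 for k in kernels):
            raise ValueError(f"SPP kernels must be odd, got {kernels}")
        self.pools = [MaxPool2d(k, stride=1) for k in kernels]

    def forward(self, x):
        self._c = x.shape[1]
        return np.concatenate([x] + [p(x) for p in self.pools], axis=1)

    def backward(self, dy):
        c = self._c
        dx = dy[:, :c].copy()
        for i, p in enumerate(self.pools):
            dx += p.backward(dy[:, (i + 1) * c : (i + 2) * c])
        return dx
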