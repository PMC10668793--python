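"""TA-enhanced MobileNetV3-style backbone.

A stride-2 CBR stem followed by six TAneck rows; output1/2/3 are tapped
after rows 2, 4 and 6 at strides 8, 16 and 32.  Feature branches of the
neck consume the three taps independently.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .blocks import CBR, TANeck
from .config import ModelConfig, default_config
from .nn import Module

__all__ = ["FeatureMap", "Backbone", "count_parameters"]


class FeatureMap(NamedTuple):
    """Activation tensor (N, C, H, W) plus its downsampling stride."""

    data: np.ndarray
    stride: int


class Backbone(Module):
    def __init__(self, cfg: ModelConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or default_config()
        self.cfg = cfg
        rng = np.random.default_rng() if rng is None else rng
        stem_out = cfg.scaled(cfg.stem_out)
        self.stem = CBR(3, stem_out, 3, stride=2, rng=rng)
        self.blocks = []
        self.out_channels = []
        self.out_strides = []
        cin, stride = stem_out, 2
        for row in cfg.backbone:
            exp, out = cfg.scaled(row.exp), cfg.scaled(row.out)
            self.blocks.append(
                TANeck(cin, exp, out, row.k, stride=row.s, use_attn=row.at,
                       use_res=row.res, attention=cfg.attention, rng=rng))
            cin = out
            stride *= row.s
            if len(self.blocks) - 1 in cfg.taps:
                self.out_channels.append(out)
                self.out_strides.append(stride)
        if tuple(self.out_strides) != (8, 16, 32):
            raise ValueError(f"tap strides must be (8, 16, 32), got {self.out_strides}")

    def forward(self, x: np.ndarray):
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial size must be divisible by 32, got {x.shape[2:]}")
        y = self.stem(x)
        outs = []
        for i, block in enumerate(self.blocks):
            y = block(y)
            if i in self.cfg.taps:
                outs.append(y)
        return tuple(FeatureMap(o, s) for o, s in zip(outs, self.out_strides))

    def backward(self, douts):
        """douts: gradients for (output1, output2, output3)."""
        taps = self.cfg.taps
        d = None
        grads = {t: g for t, g in zip(taps, douts)}
        for i in range(len(self.blocks) - 1, -1, -1):
            if i in grads:
                d = grads[i] if d is None else d + grads[i]
            d = self.blocks[i].backward(d)
        return self.stem.backward(d)


def count_parameters(module: Module) -> int:
    """Exact number of trainable scalars in a network component."""
    return module.num_parameters()
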