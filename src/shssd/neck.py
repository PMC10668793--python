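"""Feature-branch neck: three independent stacks, no cross-scale fusion.

Branch1 (stride 8): DW-CBR x2, SPP, CBR x2, TAneck x5  (10 modules).
Branch2 (stride 16): DW-CBR x2, SPP, CBR x2, TAneck x4.
Branch3 (stride 32): as Branch2 but without the SPP stage.

The first CBR after SPP reduces the quadrupled channel count to the shared
head width; spatial sizes are untouched (every op is stride 1), so the
branch outputs keep the backbone strides.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .backbone import FeatureMap
from .blocks import CBR, DWCBR, SPP, TANeck
from .config import ModelConfig, default_config
from .nn import Module, Sequential

__all__ = ["NeckOutputs", "Neck"]


class NeckOutputs(NamedTuple):
    p1: FeatureMap
    p2: FeatureMap
    p3: FeatureMap


def _branch(cin, width, exp, n_ta, use_spp, spp_kernels, rng):
    layers = [DWCBR(cin, 3, rng=rng), DWCBR(cin, 3, rng=rng)]
    c = cin
    if use_spp:
        layers.append(SPP(spp_kernels))
        c = 4 * cin
    layers.append(CBR(c, width, 1, rng=rng))        # channel reduction
    layers.append(CBR(width, width, 3, rng=rng))
    for _ in range(n_ta):
        layers.append(TANeck(width, exp, width, 5, stride=1,
                             use_attn=True, use_res=True, rng=rng))
    return Sequential(*layers)


class Neck(Module):
    def __init__(self, in_channels, cfg: ModelConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or default_config()
        self.cfg = cfg
        rng = np.random.default_rng() if rng is None else rng
        width = cfg.scaled(cfg.neck_width)
        spp_flags = (True, True, cfg.branch3_spp)
        self.branches = [
            _branch(cin, width, cfg.scaled(exp), n_ta, use_spp,
                    cfg.spp_kernels, rng)
            for cin, exp, n_ta, use_spp in zip(
                in_channels, cfg.neck_expansions, cfg.neck_tanecks, spp_flags)
        ]
        self.out_channels = (width, width, width)

    def forward(self, feats):
        if len(feats) != 3:
            raise ValueError("neck expects three backbone outputs")
        outs = []
        for branch, fm in zip(self.branches, feats):
            data = fm.data if isinstance(fm, FeatureMap) else fm
            stride = fm.stride if isinstance(fm, FeatureMap) else None
            outs.append(FeatureMap(branch(data), stride))
        return NeckOutputs(*outs)

    def backward(self, dps):
        """dps: gradients for (p1, p2, p3); returns backbone-output grads."""
        return tuple(branch.backward(d) for branch, d in zip(self.branches, dps))
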