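"""Declarative SH-SSD architecture configuration.

The published architecture fixes the module sequence (stem CBR + six
TAnecks in the backbone; three independent neck branches of DW-CBR / SPP /
CBR / TAneck stacks; three decoupled heads) and the three trainable
parameter totals (TA backbone 2.97 M, SE backbone 2.98 M, full detector
6.44 M), but not the per-layer channel widths.  The widths below follow the
MobileNetV3-Large doubling ladder and were fixed, once, so that the three
totals land on the published values; every test and audit reads this one
table.  ``width_mult`` scales all widths for reduced-size experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["TANeckConfig", "ModelConfig", "BACKBONE_TABLE", "default_config"]


@dataclass(frozen=True)
class TANeckConfig:
    """(k, s, exp, out, AT, Res) row of the backbone table."""

    k: int
    s: int
    exp: int
    out: int
    at: bool
    res: bool

    def __post_init__(self):
        if self.k not in (3, 5):
            raise ValueError(f"kernel must be 3 or 5, got {self.k}")
        if self.res and self.s != 1:
            raise ValueError("residual rows require stride 1")


#: stem CBR is 3 -> 24, k3, stride 2; taps (output1..3) follow rows 2, 4, 6,
#: giving strides 8 / 16 / 32.
BACKBONE_TABLE = (
    TANeckConfig(3, 2, 112, 56, False, False),
    TANeckConfig(3, 2, 216, 112, False, False),   # -> output1, stride 8
    TANeckConfig(5, 2, 432, 216, True, False),
    TANeckConfig(5, 1, 864, 216, True, True),     # -> output2, stride 16
    TANeckConfig(5, 2, 864, 432, False, False),
    TANeckConfig(5, 1, 1992, 432, False, True),   # -> output3, stride 32
)


@dataclass
class ModelConfig:
    image_size: int = 640
    num_classes: int = 1
    stem_out: int = 24
    backbone: tuple = BACKBONE_TABLE
    taps: tuple = (1, 3, 5)                 # backbone rows producing output1..3
    neck_width: int = 176                   # shared head input width
    neck_expansions: tuple = (368, 360, 360)  # TAneck expansion per branch
    neck_tanecks: tuple = (5, 4, 4)         # TAneck count per branch
    spp_kernels: tuple = (5, 9, 13)
    branch3_spp: bool = False               # Branch3 omits SPP
    anchors_per_cell: int = 3
    anchor_base_sizes: tuple = (32.0, 64.0, 128.0)   # per level, ratio 1:1
    anchor_scale_steps: tuple = (1.0, 2 ** (1 / 3), 2 ** (2 / 3))
    attention: str = "ta"                   # "ta" or "se" (audit variant)
    width_mult: float = 1.0

    def scaled(self, w: int) -> int:
        if self.width_mult == 1.0:
            return w
        return max(8, int(round(w * self.width_mult / 8)) * 8)

    # -- serialization --------------------------------------------------
    def to_yaml(self, path):
        d = asdict(self)
        d["backbone"] = [asdict(TANeckConfig(*row) if not isinstance(row, TANeckConfig) else row)
                         for row in self.backbone]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["backbone"] = tuple(TANeckConfig(**row) for row in d["backbone"])
        for key in ("taps", "neck_expansions", "neck_tanecks", "spp_kernels",
                    "anchor_base_sizes", "anchor_scale_steps"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_config(**overrides) -> ModelConfig:
    return ModelConfig(**overrides)
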