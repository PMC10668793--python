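"""Full SH-SSD assembly and the parameter auditor."""

from __future__ import annotations

import numpy as np

from .backbone import Backbone, count_parameters
from .config import ModelConfig, default_config
from .head import (AnchorSet, BoxSet, Head, build_anchors, decode_boxes, nms)
from .neck import Neck
from .nn import Module

__all__ = ["SHSSD", "parameter_audit"]


class SHSSD(Module):
    """Backbone + feature-branch neck + three decoupled heads.

    ``forward`` returns per-level (cls, reg) maps; ``detect`` runs the whole
    inference path (decode + NMS) on preprocessed images in [0, 1].
    """

    def __init__(self, cfg: ModelConfig | None = None, seed: int | None = None):
        super().__init__()
        self.cfg = cfg or default_config()
        rng = np.random.default_rng(seed)
        self.backbone = Backbone(self.cfg, rng=rng)
        self.neck = Neck(self.backbone.out_channels, self.cfg, rng=rng)
        self.head = Head(self.neck.out_channels, self.cfg.num_classes,
                         self.cfg.anchors_per_cell, rng=rng)
        self._anchor_cache: dict[int, AnchorSet] = {}

    def anchors(self, image_size: int) -> AnchorSet:
        if image_size not in self._anchor_cache:
            self._anchor_cache[image_size] = build_anchors(image_size, self.cfg)
        return self._anchor_cache[image_size]

    def forward(self, x: np.ndarray):
        feats = self.backbone(x)
        neck_out = self.neck(feats)
        return self.head(neck_out)

    def backward(self, dcls_maps, dreg_maps):
        dps = self.head.backward(dcls_maps, dreg_maps)
        dfeats = self.neck.backward(dps)
        return self.backbone.backward(dfeats)

    def detect(self, images: np.ndarray, score_thresh: float = 0.05,
               nms_thresh: float = 0.5) -> list[BoxSet]:
        """Inference on a (N, 3, S, S) batch of [0, 1] images."""
        was_training = self.training
        self.eval()
        try:
            cls_maps, reg_maps = self.forward(images.astype(np.float32))
        finally:
            self.train(was_training)
        size = images.shape[2]
        anchors = self.anchors(size)
        results = []
        for i in range(images.shape[0]):
            dets = decode_boxes([m[i] for m in cls_maps], [m[i] for m in reg_maps],
                                anchors, score_thresh, self.cfg.num_classes,
                                self.cfg.anchors_per_cell, image_size=size)
            results.append(nms(dets, nms_thresh))
        return results

    # -- persistence ----------------------------------------------------
    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})
        return self


def parameter_audit(cfg: ModelConfig | None = None) -> dict:
    """Trainable-parameter counts of the backbone variants and the full
    detector, raw and in millions (2 decimals)."""
    cfg = cfg or default_config()
    rng_seed = 0
    model = SHSSD(cfg, seed=rng_seed)
    se_cfg = ModelConfig(**{**vars(cfg), "attention": "se"})
    se_backbone = Backbone(se_cfg, rng=np.random.default_rng(rng_seed))
    counts = {
        "backbone_ta": count_parameters(model.backbone),
        "backbone_se": count_parameters(se_backbone),
        "neck": count_parameters(model.neck),
        "head": count_parameters(model.head),
        "total": count_parameters(model),
    }
    report = {k: {"params": int(v), "millions": round(v / 1e6, 2)}
              for k, v in counts.items()}
    n_ta_backbone = sum(1 for row in cfg.backbone if row.at)
    report["ta_blocks_backbone"] = n_ta_backbone
    report["ta_vs_se_delta"] = int(counts["backbone_se"] - counts["backbone_ta"])
    return report
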