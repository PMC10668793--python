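"""Decoupled prediction heads, anchor machinery, box coding and NMS.

Boxes are 0-based half-open ``[xmin, xmax) x [ymin, ymax)`` floats
throughout.  Anchors are square (1:1), three per cell, at per-level sizes
``base * {1, 2^(1/3), 2^(2/3)}`` for bases 32/64/128 on strides 8/16/32.
Box coding follows the SSD convention without variance scaling:
``cx = a_cx + t_x * a_w``, ``w = a_w * exp(t_w)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import CBR, DWCBR
from .config import ModelConfig, default_config
from .neck import NeckOutputs
from .nn import Conv2d, Module, Sequential

__all__ = ["BoxSet", "AnchorSet", "build_anchors", "iou", "iou_matrix",
           "encode", "decode_boxes", "nms", "DCHead", "Head"]


# ---------------------------------------------------------------------------
# boxes


@dataclass
class BoxSet:
    """Detection boxes (M, 4) xyxy with scores and integer labels."""

    boxes: np.ndarray
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if not (len(self.boxes) == len(self.scores) == len(self.labels)):
            raise ValueError("boxes, scores and labels must have equal length")

    def __len__(self):
        return len(self.boxes)

    @classmethod
    def empty(cls):
        return cls(np.zeros((0, 4)), np.zeros(0), np.zeros(0, dtype=np.int64))


@dataclass
class AnchorSet:
    """Per-level anchor grids in (cx, cy, w, h) pixel coordinates."""

    per_level: list                      # list of (H*W*A, 4) arrays
    strides: tuple

    @property
    def all(self) -> np.ndarray:
        return np.concatenate(self.per_level, axis=0)

    @property
    def level_strides(self) -> np.ndarray:
        return np.concatenate([np.full(len(a), s) for a, s in
                               zip(self.per_level, self.strides)])


def build_anchors(image_size: int, cfg: ModelConfig | None = None) -> AnchorSet:
    cfg = cfg or default_config()
    strides = (8, 16, 32)
    per_level = []
    for stride, base in zip(strides, cfg.anchor_base_sizes):
        n = image_size // stride
        cx, cy = np.meshgrid((np.arange(n) + 0.5) * stride,
                             (np.arange(n) + 0.5) * stride)
        sizes = np.array([base * s for s in cfg.anchor_scale_steps])
        # layout (H, W, A, 4), flattened in that order to match head maps
        anchors = np.zeros((n, n, len(sizes), 4))
        anchors[..., 0] = cx[:, :, None]
        anchors[..., 1] = cy[:, :, None]
        anchors[..., 2] = sizes[None, None, :]
        anchors[..., 3] = sizes[None, None, :]
        per_level.append(anchors.reshape(-1, 4))
    return AnchorSet(per_level, strides)


def iou(a, b) -> float:
    """Intersection over union of two xyxy boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(M, N) IoU between two xyxy box arrays."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    iw = np.clip(np.minimum(a[:, None, 2], b[None, :, 2])
                 - np.maximum(a[:, None, 0], b[None, :, 0]), 0, None)
    ih = np.clip(np.minimum(a[:, None, 3], b[None, :, 3])
                 - np.maximum(a[:, None, 1], b[None, :, 1]), 0, None)
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def _to_cxcywh(xyxy):
    xyxy = np.asarray(xyxy, dtype=np.float64).reshape(-1, 4)
    wh = xyxy[:, 2:] - xyxy[:, :2]
    return np.concatenate([xyxy[:, :2] + 0.5 * wh, wh], axis=1)


def _to_xyxy(cxcywh):
    cxcywh = np.asarray(cxcywh, dtype=np.float64).reshape(-1, 4)
    half = 0.5 * cxcywh[:, 2:]
    return np.concatenate([cxcywh[:, :2] - half, cxcywh[:, :2] + half], axis=1)


def encode(gt_xyxy: np.ndarray, anchors_cxcywh: np.ndarray) -> np.ndarray:
    """Regression targets (tx, ty, tw, th) for boxes against anchors."""
    g = _to_cxcywh(gt_xyxy)
    a = np.asarray(anchors_cxcywh, dtype=np.float64).reshape(-1, 4)
    t = np.empty_like(g)
    t[:, 0] = (g[:, 0] - a[:, 0]) / a[:, 2]
    t[:, 1] = (g[:, 1] - a[:, 1]) / a[:, 3]
    t[:, 2] = np.log(g[:, 2] / a[:, 2])
    t[:, 3] = np.log(g[:, 3] / a[:, 3])
    return t


def decode_offsets(t: np.ndarray, anchors_cxcywh: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode`; returns xyxy boxes."""
    a = np.asarray(anchors_cxcywh, dtype=np.float64).reshape(-1, 4)
    t = np.asarray(t, dtype=np.float64).reshape(-1, 4)
    out = np.empty_like(t)
    out[:, 0] = a[:, 0] + t[:, 0] * a[:, 2]
    out[:, 1] = a[:, 1] + t[:, 1] * a[:, 3]
    out[:, 2] = a[:, 2] * np.exp(np.clip(t[:, 2], -10, 10))
    out[:, 3] = a[:, 3] * np.exp(np.clip(t[:, 3], -10, 10))
    return _to_xyxy(out)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def flatten_maps(cls_maps, reg_maps, num_classes, anchors_per_cell):
    """Head maps -> ((M, K) logits, (M, 4) offsets) in anchor order."""
    cls_all, reg_all = [], []
    for cmap, rmap in zip(cls_maps, reg_maps):
        a, k4 = anchors_per_cell, 4
        _, h, w = cmap.shape
        cls_all.append(cmap.reshape(a, num_classes, h, w)
                       .transpose(2, 3, 0, 1).reshape(-1, num_classes))
        reg_all.append(rmap.reshape(a, k4, h, w)
                       .transpose(2, 3, 0, 1).reshape(-1, 4))
    return np.concatenate(cls_all), np.concatenate(reg_all)


def decode_boxes(cls_maps, reg_maps, anchors: AnchorSet, score_thresh: float,
                 num_classes: int = 1, anchors_per_cell: int = 3,
                 image_size: int | None = None) -> BoxSet:
    """Decode one image's head maps to thresholded, clipped boxes."""
    logits, offsets = flatten_maps(cls_maps, reg_maps, num_classes, anchors_per_cell)
    probs = _sigmoid(logits)
    labels = probs.argmax(axis=1)
    scores = probs[np.arange(len(probs)), labels]
    keep = scores >= score_thresh
    if not keep.any():
        return BoxSet.empty()
    boxes = decode_offsets(offsets[keep], anchors.all[keep])
    if image_size is not None:
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, image_size)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, image_size)
    return BoxSet(boxes, scores[keep], labels[keep])


def nms(dets: BoxSet, iou_thresh: float = 0.5) -> BoxSet:
    """Greedy class-wise suppression; ties broken by lower box index."""
    if len(dets) == 0:
        return dets
    keep = []
    for cls in np.unique(dets.labels):
        idx = np.flatnonzero(dets.labels == cls)
        order = idx[np.lexsort((idx, -dets.scores[idx]))]
        while len(order):
            i = order[0]
            keep.append(i)
            if len(order) == 1:
                break
            ious = iou_matrix(dets.boxes[i:i + 1], dets.boxes[order[1:]])[0]
            order = order[1:][ious <= iou_thresh]
    keep = np.array(sorted(keep, key=lambda i: (-dets.scores[i], i)))
    return BoxSet(dets.boxes[keep], dets.scores[keep], dets.labels[keep])


# ---------------------------------------------------------------------------
# network


class DCHead(Module):
    """Decoupled head: shared CBR stem, then disjoint classification and
    regression stacks of (DW-CBR -> CBR) x2 ending in 1x1 prediction convs."""

    def __init__(self, cin, num_classes=1, anchors_per_cell=3, rng=None):
        super().__init__()
        w = cin
        self.stem = CBR(cin, w, 1, rng=rng)
        self.cls_branch = Sequential(DWCBR(w, 3, rng=rng), CBR(w, w, 1, rng=rng),
                                     DWCBR(w, 3, rng=rng), CBR(w, w, 1, rng=rng))
        self.reg_branch = Sequential(DWCBR(w, 3, rng=rng), CBR(w, w, 1, rng=rng),
                                     DWCBR(w, 3, rng=rng), CBR(w, w, 1, rng=rng))
        self.cls_pred = Conv2d(w, anchors_per_cell * num_classes, 1, bias=True, rng=rng)
        # low-foreground-prior bias: sigmoid(b) = 0.01, so a freshly
        # initialized head is not swamped by background gradient
        self.cls_pred.bias.data[...] = float(np.log(0.01 / 0.99))
        self.reg_pred = Conv2d(w, anchors_per_cell * 4, 1, bias=True, rng=rng)

    def forward(self, p):
        s = self.stem(p)
        return (self.cls_pred(self.cls_branch(s)),
                self.reg_pred(self.reg_branch(s)))

    def backward(self, dcls, dreg):
        ds = self.cls_branch.backward(self.cls_pred.backward(dcls))
        ds = ds + self.reg_branch.backward(self.reg_pred.backward(dreg))
        return self.stem.backward(ds)


class Head(Module):
    """Three DCHeads aligned with the three neck branches."""

    def __init__(self, in_channels, num_classes=1, anchors_per_cell=3, rng=None):
        super().__init__()
        rng = np.random.default_rng() if rng is None else rng
        self.num_classes = num_classes
        self.anchors_per_cell = anchors_per_cell
        self.heads = [DCHead(c, num_classes, anchors_per_cell, rng=rng)
                      for c in in_channels]

    def forward(self, neck_out: NeckOutputs):
        cls_maps, reg_maps = [], []
        for head, fm in zip(self.heads, neck_out):
            c, r = head(fm.data)
            cls_maps.append(c)
            reg_maps.append(r)
        return cls_maps, reg_maps

    def backward(self, dcls_maps, dreg_maps):
        return tuple(head.backward(dc, dr)
                     for head, dc, dr in zip(self.heads, dcls_maps, dreg_maps))
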