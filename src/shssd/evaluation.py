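"""Detection evaluation: precision, recall, PR curves and average precision.

``P = TP / (TP + FP) * 100`` and ``R = TP / (TP + FN) * 100``; AP is the
area under the interpolated precision-recall curve.  Dataset-level AP uses
the COCO convention: IoU thresholds 0.50:0.05:0.95, 101-point recall
interpolation, and a small-object stratum for ground truths with area
below 32 x 32 px.  ``average_precision`` on explicit PR points integrates
the interpolated curve exactly (the 101-point grid is applied by
``evaluate_detections``); the two agree to within the grid quantization.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .head import BoxSet, iou_matrix

__all__ = ["EvalCounts", "EvalResult", "match_detections", "precision",
           "recall", "average_precision", "pr_curve", "evaluate_detections",
           "small_target_ap", "to_coco_json", "from_coco_json",
           "measure_fps", "COCO_IOU_THRESHOLDS", "SMALL_AREA_MAX"]

COCO_IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))
SMALL_AREA_MAX = 32 * 32


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class EvalResult:
    precision: float            # percent, at IoU 0.5 over all supplied dets
    recall: float               # percent, mean recall over the IoU range
    ap_per_iou: dict            # IoU threshold -> AP percent
    ap50: float
    ap: float                   # AP0.5:0.95 percent
    ap_small: float             # small-target AP0.5:0.95 percent (NaN if empty)
    curves: dict = field(default_factory=dict)


def _greedy_match_flags(dets: BoxSet, gt_boxes: np.ndarray, iou_thresh: float):
    """Score-ranked greedy one-to-one matching.  Returns a bool TP flag per
    detection (in the BoxSet's order)."""
    m = len(dets)
    flags = np.zeros(m, dtype=bool)
    if m == 0 or len(gt_boxes) == 0:
        return flags
    order = np.lexsort((np.arange(m), -dets.scores))
    ious = iou_matrix(dets.boxes, gt_boxes)
    taken = np.zeros(len(gt_boxes), dtype=bool)
    for di in order:
        row = ious[di].copy()
        row[taken] = -1.0
        gi = int(np.argmax(row))
        if row[gi] >= iou_thresh:
            flags[di] = True
            taken[gi] = True
    return flags


def match_detections(dets: BoxSet, gts: BoxSet | np.ndarray,
                     iou_thresh: float = 0.5) -> EvalCounts:
    """TP/FP/FN of one detection set against one ground-truth set."""
    gt_boxes = gts.boxes if isinstance(gts, BoxSet) else \
        np.asarray(gts, dtype=np.float64).reshape(-1, 4)
    flags = _greedy_match_flags(dets, gt_boxes, iou_thresh)
    tp = int(flags.sum())
    return EvalCounts(tp=tp, fp=len(dets) - tp, fn=len(gt_boxes) - tp)


def precision(c: EvalCounts) -> float:
    """Eq.: P = TP / (TP + FP) x 100%; defined as 0 when no detections."""
    denom = c.tp + c.fp
    return 100.0 * c.tp / denom if denom else 0.0


def recall(c: EvalCounts) -> float:
    """Eq.: R = TP / (TP + FN) x 100%; 0 when there are no ground truths."""
    denom = c.tp + c.fn
    return 100.0 * c.tp / denom if denom else 0.0


def pr_curve(per_image: list, iou_thresh: float = 0.5):
    """``per_image``: list of (BoxSet dets, gt boxes).  Returns (recalls,
    precisions) swept over the global score ranking."""
    scores, flags = [], []
    n_gt = 0
    for dets, gts in per_image:
        gt_boxes = gts.boxes if isinstance(gts, BoxSet) else \
            np.asarray(gts, dtype=np.float64).reshape(-1, 4)
        n_gt += len(gt_boxes)
        if len(dets):
            scores.append(dets.scores)
            flags.append(_greedy_match_flags(dets, gt_boxes, iou_thresh))
    if not scores or n_gt == 0:
        return np.zeros(0), np.zeros(0)
    scores = np.concatenate(scores)
    flags = np.concatenate(flags)
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(flags[order])
    fp = np.cumsum(~flags[order])
    recalls = tp / n_gt
    precisions = tp / np.maximum(tp + fp, 1)
    return recalls, precisions


def average_precision(recalls, precisions, n_points: int | None = None) -> float:
    """Area under the interpolated PR curve, in percent.

    With ``n_points`` (e.g. 101 for the COCO rule) precision is sampled on
    an even recall grid; otherwise the interpolated curve is integrated
    exactly over the recall steps."""
    recalls = np.asarray(recalls, dtype=np.float64)
    precisions = np.asarray(precisions, dtype=np.float64)
    if recalls.size == 0:
        return 0.0
    order = np.argsort(recalls, kind="stable")
    r = np.concatenate([[0.0], recalls[order]])
    p = np.concatenate([[0.0], precisions[order]])
    # right-to-left running max: interpolated precision
    p_interp = np.maximum.accumulate(p[::-1])[::-1]
    if n_points is not None:
        grid = np.linspace(0, 1, n_points)
        idx = np.searchsorted(r, grid, side="left")
        vals = np.where(idx < len(r), p_interp[np.minimum(idx, len(r) - 1)], 0.0)
        vals[grid > r[-1]] = 0.0
        return float(vals.mean() * 100.0)
    return float(np.sum(np.diff(r) * p_interp[1:]) * 100.0)


def _filter_small(per_image):
    out = []
    for dets, gts in per_image:
        gt_boxes = gts.boxes if isinstance(gts, BoxSet) else \
            np.asarray(gts, dtype=np.float64).reshape(-1, 4)
        if len(gt_boxes):
            area = (gt_boxes[:, 2] - gt_boxes[:, 0]) * (gt_boxes[:, 3] - gt_boxes[:, 1])
            gt_boxes = gt_boxes[area < SMALL_AREA_MAX]
        out.append((dets, gt_boxes))
    return out


def small_target_ap(per_image: list,
                    iou_thresholds=COCO_IOU_THRESHOLDS) -> float:
    """AP over ground truths with area < 32 x 32 px; NaN when the stratum
    is empty."""
    filtered = _filter_small(per_image)
    if sum(len(g) for _, g in filtered) == 0:
        return float("nan")
    aps = [average_precision(*pr_curve(filtered, t), n_points=101)
           for t in iou_thresholds]
    return float(np.mean(aps))


def evaluate_detections(per_image: list,
                        iou_thresholds=COCO_IOU_THRESHOLDS) -> EvalResult:
    """Full evaluation of per-image (detections, ground-truth boxes)."""
    ap_per_iou = {}
    recalls_at = []
    curves = {}
    for t in iou_thresholds:
        r, p = pr_curve(per_image, t)
        ap_per_iou[float(t)] = average_precision(r, p, n_points=101)
        recalls_at.append(100.0 * (r[-1] if len(r) else 0.0))
        curves[float(t)] = (r, p)
    counts50 = EvalCounts(0, 0, 0)
    for dets, gts in per_image:
        c = match_detections(dets, gts, 0.5)
        counts50.tp += c.tp
        counts50.fp += c.fp
        counts50.fn += c.fn
    ap50 = ap_per_iou.get(0.5, next(iter(ap_per_iou.values())))
    return EvalResult(
        precision=precision(counts50),
        recall=float(np.mean(recalls_at)),
        ap_per_iou=ap_per_iou,
        ap50=ap50,
        ap=float(np.mean(list(ap_per_iou.values()))),
        ap_small=small_target_ap(per_image, iou_thresholds),
        curves=curves,
    )


def to_coco_json(per_image: list, category: str = "sheep") -> dict:
    """Per-image (detections, ground truths) -> a COCO-style dict with
    images / annotations / detections sections (xywh boxes)."""
    images, annotations, detections = [], [], []
    ann_id = 1
    for img_id, (dets, gts) in enumerate(per_image, start=1):
        images.append({"id": img_id})
        gt_boxes = gts.boxes if isinstance(gts, BoxSet) else \
            np.asarray(gts, dtype=np.float64).reshape(-1, 4)
        for b in gt_boxes:
            annotations.append({
                "id": ann_id, "image_id": img_id, "category_id": 1,
                "bbox": [b[0], b[1], b[2] - b[0], b[3] - b[1]],
                "area": float((b[2] - b[0]) * (b[3] - b[1])),
                "iscrowd": 0})
            ann_id += 1
        for b, s in zip(dets.boxes, dets.scores):
            detections.append({
                "image_id": img_id, "category_id": 1,
                "bbox": [b[0], b[1], b[2] - b[0], b[3] - b[1]],
                "score": float(s)})
    return {"images": images,
            "categories": [{"id": 1, "name": category}],
            "annotations": annotations, "detections": detections}


def from_coco_json(payload: dict) -> list:
    """Inverse of :func:`to_coco_json`: rebuild per-image (BoxSet, gt)."""
    ids = [img["id"] for img in payload["images"]]
    gts = {i: [] for i in ids}
    dets = {i: ([], []) for i in ids}
    for ann in payload.get("annotations", []):
        x, y, w, h = ann["bbox"]
        gts[ann["image_id"]].append([x, y, x + w, y + h])
    for det in payload.get("detections", []):
        x, y, w, h = det["bbox"]
        dets[det["image_id"]][0].append([x, y, x + w, y + h])
        dets[det["image_id"]][1].append(det["score"])
    out = []
    for i in ids:
        boxes, scores = dets[i]
        boxset = BoxSet(np.array(boxes).reshape(-1, 4), np.array(scores),
                        np.zeros(len(boxes), dtype=np.int64)) if boxes \
            else BoxSet.empty()
        out.append((boxset, np.array(gts[i]).reshape(-1, 4)))
    return out


def measure_fps(detect_fn, images, repeats: int = 1) -> float:
    """FPS = M / S: images detected per second of wall time."""
    m = 0
    start = time.perf_counter()
    for _ in range(repeats):
        for img in images:
            detect_fn(img)
            m += 1
    return m / max(time.perf_counter() - start, 1e-9)
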