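"""Training-time dynamic sample matching and the detection loss.

The published method names Dynamic Sample Matching but prints no rule, so
this module implements the documented SimOTA-style reconstruction:
candidate anchors have their center inside a ground-truth box or within a
center region of ``center_radius`` cells; the assignment cost is
``-log p + lam * (-log IoU)``; each ground truth takes its k lowest-cost
candidates with ``k = clamp(floor(sum of top-10 candidate IoUs), 1, 10)``;
an anchor claimed by several ground truths goes to the cheapest one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .head import AnchorSet, encode, iou_matrix

__all__ = ["Assignment", "dynamic_match", "detection_loss"]

_EPS = 1e-9
_NON_CANDIDATE_PENALTY = 1e5


IGNORE = -2
NEGATIVE = -1


@dataclass
class Assignment:
    """Per-anchor assignment: ``anchor_gt[m]`` is the matched ground-truth
    index, -1 for negatives, or -2 for ignored anchors (candidates that
    were not selected; excluded from the classification loss so that the
    features shared with adjacent positives are not pulled both ways)."""

    anchor_gt: np.ndarray            # (M,) int
    targets: np.ndarray              # (M, 4) float, valid where anchor_gt >= 0
    cost: np.ndarray | None = None   # (G, M) diagnostics

    @property
    def positive(self) -> np.ndarray:
        return self.anchor_gt >= 0

    @property
    def negative(self) -> np.ndarray:
        return self.anchor_gt == NEGATIVE

    @property
    def ignored(self) -> np.ndarray:
        return self.anchor_gt == IGNORE

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())


def dynamic_match(pred_boxes: np.ndarray, pred_scores: np.ndarray,
                  gt_boxes: np.ndarray, anchors: AnchorSet,
                  center_radius: float = 2.5, lam: float = 3.0,
                  topk: int = 10, ignore_iou: float = 0.4,
                  keep_cost: bool = False) -> Assignment:
    """Assign anchors to ground-truth boxes given current predictions."""
    a = anchors.all
    strides = anchors.level_strides
    m = len(a)
    gt = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    g = len(gt)
    targets = np.zeros((m, 4))
    if g == 0:
        return Assignment(np.full(m, -1, dtype=np.int64), targets)

    acx, acy = a[:, 0], a[:, 1]
    in_box = ((acx[None] >= gt[:, 0, None]) & (acx[None] < gt[:, 2, None])
              & (acy[None] >= gt[:, 1, None]) & (acy[None] < gt[:, 3, None]))
    gcx = 0.5 * (gt[:, 0] + gt[:, 2])
    gcy = 0.5 * (gt[:, 1] + gt[:, 3])
    r = center_radius * strides[None]
    in_center = ((np.abs(acx[None] - gcx[:, None]) < r)
                 & (np.abs(acy[None] - gcy[:, None]) < r))
    candidate = in_box | in_center

    ious = iou_matrix(gt, np.asarray(pred_boxes, dtype=np.float64))
    cls_cost = -np.log(np.clip(np.asarray(pred_scores, dtype=np.float64),
                               _EPS, 1.0))
    cost = (cls_cost[None] + lam * -np.log(np.maximum(ious, _EPS))
            + _NON_CANDIDATE_PENALTY * (~candidate))

    # dynamic k per ground truth
    anchor_gt = np.full(m, -1, dtype=np.int64)
    best_cost = np.full(m, np.inf)
    for gi in range(g):
        cand = np.flatnonzero(candidate[gi])
        if len(cand) == 0:
            continue
        cand_ious = np.sort(ious[gi, cand])[::-1][:topk]
        k = int(np.clip(np.floor(cand_ious.sum()), 1, min(topk, len(cand))))
        picks = cand[np.argsort(cost[gi, cand], kind="stable")[:k]]
        for mi in picks:
            if cost[gi, mi] < best_cost[mi]:      # conflict: cheapest gt wins
                anchor_gt[mi] = gi
                best_cost[mi] = cost[gi, mi]

    # every ground truth with candidates keeps at least one positive
    for gi in range(g):
        if (anchor_gt == gi).any():
            continue
        cand = np.flatnonzero(candidate[gi])
        if len(cand) == 0:
            continue
        for mi in cand[np.argsort(cost[gi, cand], kind="stable")]:
            other = anchor_gt[mi]
            if other < 0 or (anchor_gt == other).sum() > 1:
                anchor_gt[mi] = gi
                break

    # ignore band: unassigned anchors whose own box overlaps a ground truth
    # substantially are genuinely ambiguous — excluding them from the
    # negatives keeps adjacent positives from being pulled both ways, while
    # low-overlap anchors still receive background supervision
    anc_xyxy = np.stack([a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2,
                         a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2], axis=1)
    anchor_gt_iou = iou_matrix(gt, anc_xyxy).max(axis=0)
    anchor_gt[(anchor_gt_iou >= ignore_iou) & (anchor_gt < 0)] = IGNORE
    pos = anchor_gt >= 0
    if pos.any():
        targets[pos] = encode(gt[anchor_gt[pos]], a[pos])
    return Assignment(anchor_gt, targets, cost if keep_cost else None)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def _smooth_l1(d, beta=1.0):
    ad = np.abs(d)
    return np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)


def _smooth_l1_grad(d, beta=1.0):
    return np.clip(d / beta, -1.0, 1.0)


def detection_loss(cls_logits: np.ndarray, reg_preds: np.ndarray,
                   assignment: Assignment, hard_neg_ratio: float = 3.0):
    """Hard-negative-mined binary cross-entropy + smooth-L1 on offsets.

    Returns ``(cls_loss, reg_loss, dcls, dreg)``; the gradients are with
    respect to the raw logits / offsets and already normalized by the
    positive count, ready to feed the network backward pass."""
    cls_logits = np.asarray(cls_logits, dtype=np.float64).reshape(len(reg_preds), -1)
    reg_preds = np.asarray(reg_preds, dtype=np.float64).reshape(-1, 4)
    pos = assignment.positive
    n_pos = max(int(pos.sum()), 1)
    p = _sigmoid(cls_logits[:, 0])

    pos_loss = -np.log(np.clip(p[pos], _EPS, 1.0))
    neg_idx = np.flatnonzero(assignment.negative)
    neg_loss_all = -np.log(np.clip(1.0 - p[neg_idx], _EPS, 1.0))
    n_neg = min(len(neg_idx), int(hard_neg_ratio * n_pos)) if pos.any() \
        else min(len(neg_idx), int(hard_neg_ratio))
    hard = neg_idx[np.argsort(-neg_loss_all, kind="stable")[:n_neg]]
    cls_loss = (pos_loss.sum() + -np.log(np.clip(1.0 - p[hard], _EPS, 1.0)).sum()) / n_pos

    dcls = np.zeros_like(cls_logits)
    dcls[pos, 0] = (p[pos] - 1.0) / n_pos
    dcls[hard, 0] = p[hard] / n_pos

    dreg = np.zeros_like(reg_preds)
    reg_loss = 0.0
    if pos.any():
        diff = reg_preds[pos] - assignment.targets[pos]
        reg_loss = _smooth_l1(diff).sum() / n_pos
        dreg[pos] = _smooth_l1_grad(diff) / n_pos
    return float(cls_loss), float(reg_loss), dcls, dreg
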