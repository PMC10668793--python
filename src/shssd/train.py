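"""Training: Adam with step-decayed learning rate, dynamic sample matching
for label assignment, hard-negative-mined BCE + smooth-L1 loss.

The full-scale schedule mirrors the published recipe (Adam, initial lr
5e-4, decay x0.1 every 100 epochs, batch 32, 300 epochs); the ``overfit``
helper runs the same loop at toy scale to verify the assign / loss /
decode path end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .assign import detection_loss, dynamic_match
from .evaluation import evaluate_detections
from .head import decode_offsets, flatten_maps
from .model import SHSSD
from .nn import Adam

__all__ = ["TrainConfig", "Trainer", "overfit"]


@dataclass
class TrainConfig:
    lr: float = 5e-4
    batch_size: int = 32
    epochs: int = 300
    lr_decay_every: int = 100
    lr_decay: float = 0.1
    hard_neg_ratio: float = 3.0
    seed: int = 0


def _batch_flatten(cls_maps, reg_maps, num_classes, a):
    """(N, A*C, H, W) level maps -> (N, M, C) logits and (N, M, 4) offsets
    in anchor order (level, row, col, anchor)."""
    n = cls_maps[0].shape[0]
    cls_all, reg_all = [], []
    for cmap, rmap in zip(cls_maps, reg_maps):
        _, _, h, w = cmap.shape
        cls_all.append(cmap.reshape(n, a, num_classes, h, w)
                       .transpose(0, 3, 4, 1, 2).reshape(n, -1, num_classes))
        reg_all.append(rmap.reshape(n, a, 4, h, w)
                       .transpose(0, 3, 4, 1, 2).reshape(n, -1, 4))
    return np.concatenate(cls_all, axis=1), np.concatenate(reg_all, axis=1)


def _batch_unflatten(dcls, dreg, shapes, num_classes, a):
    """Inverse of :func:`_batch_flatten` for the gradient tensors."""
    n = dcls.shape[0]
    dcls_maps, dreg_maps = [], []
    offset = 0
    for (_, _, h, w) in shapes:
        m = h * w * a
        dc = dcls[:, offset : offset + m].reshape(n, h, w, a, num_classes) \
            .transpose(0, 3, 4, 1, 2).reshape(n, a * num_classes, h, w)
        dr = dreg[:, offset : offset + m].reshape(n, h, w, a, 4) \
            .transpose(0, 3, 4, 1, 2).reshape(n, a * 4, h, w)
        dcls_maps.append(np.ascontiguousarray(dc, dtype=np.float32))
        dreg_maps.append(np.ascontiguousarray(dr, dtype=np.float32))
        offset += m
    return dcls_maps, dreg_maps


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class Trainer:
    def __init__(self, model: SHSSD, cfg: TrainConfig | None = None):
        self.model = model
        self.cfg = cfg or TrainConfig()
        self.opt = Adam(model.parameters(), lr=self.cfg.lr)
        self.history: list[dict] = []

    def set_lr(self, epoch: int):
        decays = epoch // self.cfg.lr_decay_every
        self.opt.lr = self.cfg.lr * (self.cfg.lr_decay ** decays)

    def step(self, images: np.ndarray, gt_boxes_per_image: list) -> dict:
        """One optimizer step on a (N, 3, S, S) batch in [0, 1]."""
        model, cfg = self.model, self.cfg
        model.train()
        cls_maps, reg_maps = model.forward(images.astype(np.float32))
        shapes = [m.shape for m in cls_maps]
        a = model.cfg.anchors_per_cell
        k = model.cfg.num_classes
        logits, offsets = _batch_flatten(cls_maps, reg_maps, k, a)
        anchors = model.anchors(images.shape[2])

        n = images.shape[0]
        dcls = np.zeros_like(logits)
        dreg = np.zeros_like(offsets)
        cls_loss = reg_loss = 0.0
        n_pos = 0
        for i in range(n):
            scores = _sigmoid(logits[i, :, 0])
            pred_boxes = decode_offsets(offsets[i], anchors.all)
            assignment = dynamic_match(pred_boxes, scores,
                                       gt_boxes_per_image[i], anchors)
            cl, rl, dc, dr = detection_loss(logits[i], offsets[i], assignment,
                                            cfg.hard_neg_ratio)
            cls_loss += cl
            reg_loss += rl
            n_pos += assignment.n_positive
            dcls[i], dreg[i] = dc, dr
        dcls /= n
        dreg /= n
        dcls_maps, dreg_maps = _batch_unflatten(dcls, dreg, shapes, k, a)
        model.zero_grad()
        model.backward(dcls_maps, dreg_maps)
        self.opt.step()
        rec = {"cls_loss": cls_loss / n, "reg_loss": reg_loss / n,
               "loss": (cls_loss + reg_loss) / n, "n_pos": n_pos,
               "lr": self.opt.lr}
        self.history.append(rec)
        return rec

    def fit(self, images: np.ndarray, gt_boxes_per_image: list,
            epochs: int | None = None, log_path=None):
        """Epoch loop over a small in-memory dataset."""
        cfg = self.cfg
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed)
        n = len(images)
        logs = []
        for epoch in range(epochs):
            self.set_lr(epoch)
            order = rng.permutation(n)
            ep = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                ep.append(self.step(images[idx], [gt_boxes_per_image[i] for i in idx]))
            rec = {"epoch": epoch,
                   "loss": float(np.mean([r["loss"] for r in ep])),
                   "lr": self.opt.lr}
            logs.append(rec)
            if log_path:
                with open(log_path, "a") as fh:
                    fh.write(json.dumps(rec) + "\n")
        return logs


def overfit(model: SHSSD, images: np.ndarray, gt_boxes_per_image: list,
            steps: int = 300, lr: float = 5e-3, batch_size: int = 2,
            seed: int = 0, eval_every: int = 25, target_ap50: float | None = None,
            score_thresh: float = 0.05, verbose: bool = False):
    """Overfit a small image set; optionally stop early once the train-set
    AP0.5 reaches ``target_ap50``.  Returns (history, final AP0.5)."""
    cfg = TrainConfig(lr=lr, batch_size=batch_size, epochs=1,
                      lr_decay_every=10 ** 9, seed=seed)
    trainer = Trainer(model, cfg)
    rng = np.random.default_rng(seed)
    n = len(images)
    ap50 = 0.0
    for step_i in range(1, steps + 1):
        # step-decayed schedule, scaled to the toy run length
        if step_i == int(steps * 0.6):
            trainer.opt.lr = lr * 0.1
        elif step_i == int(steps * 0.85):
            trainer.opt.lr = lr * 0.01
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        rec = trainer.step(images[idx], [gt_boxes_per_image[i] for i in idx])
        if verbose and step_i % 10 == 0:
            print(f"step {step_i}: loss={rec['loss']:.3f} n_pos={rec['n_pos']}")
        if step_i % eval_every == 0 or step_i == steps:
            ap50 = _train_ap50(model, images, gt_boxes_per_image, score_thresh)
            if verbose:
                print(f"step {step_i}: train AP0.5 = {ap50:.1f}")
            if target_ap50 is not None and ap50 >= target_ap50:
                break
    return trainer.history, ap50


def _train_ap50(model, images, gt_boxes_per_image, score_thresh=0.05,
                batch: int = 4):
    # re-estimate BN running statistics under the current weights: at batch
    # size 2 the stored moments lag the fast-moving toy optimization
    model.train()
    for start in range(0, min(len(images), 8), batch):
        model.forward(images[start : start + batch].astype(np.float32))
    per_image = []
    for start in range(0, len(images), batch):
        dets = model.detect(images[start : start + batch],
                            score_thresh=score_thresh)
        for d, g in zip(dets, gt_boxes_per_image[start : start + batch]):
            per_image.append((d, g))
    return evaluate_detections(per_image, iou_thresholds=(0.5,)).ap50
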