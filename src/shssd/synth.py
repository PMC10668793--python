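"""Synthetic corridor scenes: an overhead fixed camera watching head-like
targets stream top-to-bottom through a passage wide enough for four
abreast.

Heads are rendered as filled ellipses with a per-track hue and speckle
texture (so histogram appearance embeddings are discriminative); ground
truth carries persistent track ids and, per track, whether its center
trajectory crosses the counting line downward.  A detector-noise model
(misses, false positives, corner jitter) turns the truth into realistic
detection streams, which lets the tracking and counting stages be tested
without a trained network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .head import BoxSet
from .io import AnnotatedImage, write_image, write_voc_xml

__all__ = ["SceneConfig", "SceneTruth", "generate_scene", "degrade_detections",
           "export_scene", "default_line"]


@dataclass(frozen=True)
class SceneConfig:
    n_tracks: int = 4                    # up to 4 abreast per the corridor width
    frame_size: tuple = (640, 640)       # (W, H)
    n_frames: int = 160
    speed: tuple = (3.0, 6.0)            # px/frame downward
    head_size: tuple = (36, 64)          # ellipse major axis range, px
    lateral_drift: float = 0.8           # px/frame sideways jitter scale
    occlusion_prob: float = 0.2          # chance two lanes overlap
    min_visibility: float = 0.5          # record truth once this box fraction shows
    miss_rate: float = 0.0
    fp_rate: float = 0.0
    jitter_sigma: float = 0.0            # box corner noise, px
    seed: int = 0

    def __post_init__(self):
        for name in ("occlusion_prob", "miss_rate", "fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.head_size) <= 0 or min(self.frame_size) <= 0:
            raise ValueError("sizes must be positive")


@dataclass
class SceneTruth:
    """Per-frame ground truth and per-track crossing flags."""

    frames: list                          # frames[i] = list of (track_id, xyxy box)
    crossings: dict                       # track_id -> bool (crossed line downward)
    line_y: float
    config: SceneConfig

    @property
    def n_crossings(self) -> int:
        return sum(bool(v) for v in self.crossings.values())

    def boxes_at(self, i) -> BoxSet:
        entries = self.frames[i]
        if not entries:
            return BoxSet.empty()
        boxes = np.array([b for _, b in entries])
        return BoxSet(boxes, np.ones(len(entries)), np.zeros(len(entries), dtype=np.int64))


def default_line(cfg: SceneConfig) -> float:
    return cfg.frame_size[1] / 2.0


def _track_paths(cfg: SceneConfig, rng: np.random.Generator):
    """Plan center trajectories; heads enter above the frame on staggered
    frames and move down with per-track speed and lateral drift."""
    w, h = cfg.frame_size
    lanes = np.linspace(0.15 * w, 0.85 * w, num=max(cfg.n_tracks, 1))
    rng.shuffle(lanes)
    paths = []
    for t in range(cfg.n_tracks):
        lane = lanes[t % len(lanes)]
        if rng.random() < cfg.occlusion_prob and t > 0:
            lane = paths[-1]["lane"] + rng.uniform(-0.05, 0.05) * w
        speed = rng.uniform(*cfg.speed)
        start_frame = int(rng.integers(0, max(1, cfg.n_frames // 5)))
        major = rng.uniform(*cfg.head_size)
        minor = major * rng.uniform(0.7, 0.9)
        phase = rng.uniform(0, 2 * np.pi)
        y0 = -major                                  # spawn above the frame
        paths.append(dict(lane=lane, speed=speed, start=start_frame,
                          major=major, minor=minor, phase=phase, y0=y0,
                          hue=rng.uniform(0, 1)))
    return paths


def generate_scene(cfg: SceneConfig, render: bool = True):
    """Build a scene; returns (frames, truth) where frames is a list of
    H x W x 3 uint8 arrays (empty list when ``render`` is False)."""
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.frame_size
    paths = _track_paths(cfg, rng)
    line_y = default_line(cfg)

    per_frame = []
    centers: dict[int, list] = {t: [] for t in range(cfg.n_tracks)}
    for i in range(cfg.n_frames):
        entries = []
        for tid, p in enumerate(paths):
            dt = i - p["start"]
            if dt < 0:
                continue
            cy = p["y0"] + p["speed"] * dt
            cx = p["lane"] + cfg.lateral_drift * p["speed"] * np.sin(
                0.15 * dt + p["phase"])
            if cy - p["minor"] / 2 > h:              # fully exited
                continue
            box = np.array([cx - p["major"] / 2, cy - p["minor"] / 2,
                            cx + p["major"] / 2, cy + p["minor"] / 2])
            clipped = np.array([max(box[0], 0), max(box[1], 0),
                                min(box[2], w), min(box[3], h)])
            if clipped[2] - clipped[0] < 2 or clipped[3] - clipped[1] < 2:
                continue
            visible = ((clipped[2] - clipped[0]) * (clipped[3] - clipped[1])
                       / (p["major"] * p["minor"]))
            if visible < cfg.min_visibility:   # heavily truncated: unannotated
                continue
            centers[tid].append(((clipped[0] + clipped[2]) / 2,
                                 (clipped[1] + clipped[3]) / 2))
            entries.append((tid, clipped))
        per_frame.append(entries)

    crossings = {}
    for tid, cs in centers.items():
        ys = [c[1] for c in cs]
        crossings[tid] = any(a < line_y and b > line_y
                             for a, b in zip(ys, ys[1:]))

    truth = SceneTruth(per_frame, crossings, line_y, cfg)

    frames = []
    if render:
        texture_rng = np.random.default_rng(cfg.seed + 1)
        background = texture_rng.integers(70, 90, size=(h, w, 3)).astype(np.uint8)
        for i in range(cfg.n_frames):
            img = Image.fromarray(background.copy())
            draw = ImageDraw.Draw(img)
            # fixed z-order: higher track id drawn on top
            for tid, box in sorted(per_frame[i], key=lambda e: e[0]):
                color = _hue_rgb(paths[tid]["hue"])
                draw.ellipse(tuple(box), fill=color)
            arr = np.asarray(img).astype(np.int16)
            speckle = texture_rng.integers(-12, 13, size=(h, w, 1))
            frames.append(np.clip(arr + speckle, 0, 255).astype(np.uint8))
    return frames, truth


def _hue_rgb(hue: float) -> tuple:
    import colorsys

    r, g, b = colorsys.hsv_to_rgb(hue, 0.55, 0.85)
    return int(r * 255), int(g * 255), int(b * 255)


def degrade_detections(truth: SceneTruth, cfg: SceneConfig | None = None,
                       rng: np.random.Generator | None = None) -> list:
    """Truth boxes -> noisy per-frame BoxSets: misses at ``miss_rate``,
    uniform false positives at ``fp_rate`` per frame, Gaussian corner
    jitter.  Seeded via ``rng`` (falls back to the scene seed)."""
    cfg = cfg or truth.config
    rng = rng or np.random.default_rng(cfg.seed + 2)
    w, h = cfg.frame_size
    streams = []
    for entries in truth.frames:
        boxes, scores = [], []
        for _, box in entries:
            if rng.random() < cfg.miss_rate:
                continue
            b = box + rng.normal(0, cfg.jitter_sigma, size=4) \
                if cfg.jitter_sigma > 0 else box.copy()
            if b[2] <= b[0] or b[3] <= b[1]:
                continue
            boxes.append(b)
            scores.append(rng.uniform(0.6, 1.0))
        if rng.random() < cfg.fp_rate:
            size = rng.uniform(*cfg.head_size)
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            boxes.append(np.array([cx - size / 2, cy - size / 2,
                                   cx + size / 2, cy + size / 2]))
            scores.append(rng.uniform(0.3, 0.7))
        if boxes:
            streams.append(BoxSet(np.array(boxes), np.array(scores),
                                  np.zeros(len(boxes), dtype=np.int64)))
        else:
            streams.append(BoxSet.empty())
    return streams


def make_detection_dataset(n_images: int, image_size: int = 320, seed: int = 0,
                           max_tracks: int = 5):
    """Sample rendered frames that contain at least one head.

    Returns ``(images, gt_boxes)``: a (N, 3, S, S) float32 array in [0, 1]
    and a list of (G_i, 4) ground-truth box arrays."""
    rng = np.random.default_rng(seed)
    images, gt_boxes = [], []
    scene_seed = seed
    while len(images) < n_images:
        cfg = SceneConfig(n_tracks=int(rng.integers(1, max_tracks + 1)),
                          frame_size=(image_size, image_size),
                          n_frames=40, seed=scene_seed)
        frames, truth = generate_scene(cfg, render=True)
        candidates = [i for i, e in enumerate(truth.frames) if e]
        rng.shuffle(candidates)
        for i in candidates[:4]:
            if len(images) >= n_images:
                break
            images.append(frames[i].transpose(2, 0, 1).astype(np.float32) / 255.0)
            gt_boxes.append(np.array([b for _, b in truth.frames[i]]))
        scene_seed += 1
    return np.stack(images), gt_boxes


def export_scene(out_dir, frames, truth: SceneTruth, label: str = "sheep"):
    """Write frames as PNG + per-frame VOC XML + a truth JSON."""
    import json

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    w, h = truth.config.frame_size
    for i, entries in enumerate(truth.frames):
        name = f"frame_{i:05d}"
        if frames:
            write_image(out / "images" / f"{name}.png", frames[i])
        boxes = np.array([b for _, b in entries]).reshape(-1, 4)
        ann = AnnotatedImage(None, boxes, [label] * len(entries),
                             source_path=str(out / "images" / f"{name}.png"))
        write_voc_xml(out / "annotations" / f"{name}.xml", ann,
                      image_size=(w, h), filename=f"{name}.png")
    payload = {
        "line_y": truth.line_y,
        "n_crossings": truth.n_crossings,
        "crossings": {str(k): bool(v) for k, v in truth.crossings.items()},
        "frames": [[[int(tid), [float(v) for v in box]] for tid, box in entries]
                   for entries in truth.frames],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh)
    return out
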