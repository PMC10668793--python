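"""DeepSort-style tracking-by-detection.

A constant-velocity Kalman filter runs on the (cx, cy, aspect, height)
measurement of each head box; confirmed tracks are matched to detections
by a matching cascade (most recently updated first) on a cost that blends
the chi-square-gated Mahalanobis distance with an appearance distance,
solved with the Hungarian algorithm; leftovers fall back to IoU matching.

The original appearance term uses a trained re-identification CNN; here
the default embedding is an 8x8x8 RGB histogram of the box crop (cosine
distance), with ``embed_fn`` as the plug-in point for a learned model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.linalg
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2

from .head import BoxSet, iou_matrix

__all__ = ["KalmanFilter", "KalmanState", "Track", "TrackStatus", "Tracker",
           "associate", "histogram_embedding", "GATE_CHI2_99_DF4"]

#: 99% chi-square quantile, 4 degrees of freedom (measurement dimension)
GATE_CHI2_99_DF4 = float(chi2.ppf(0.99, 4))


@dataclass
class KalmanState:
    """Mean (cx, cy, a, h, and velocities) and 8x8 covariance."""

    mean: np.ndarray
    cov: np.ndarray


class KalmanFilter:
    """Constant-velocity filter with height-scaled noise, as in DeepSort."""

    def __init__(self, std_weight_pos: float = 1.0 / 20,
                 std_weight_vel: float = 1.0 / 160):
        self.wp, self.wv = std_weight_pos, std_weight_vel
        self.F = np.eye(8)
        self.F[:4, 4:] = np.eye(4)
        self.H = np.eye(4, 8)

    def initiate(self, measurement: np.ndarray) -> KalmanState:
        m = np.asarray(measurement, dtype=np.float64)
        mean = np.concatenate([m, np.zeros(4)])
        h = max(m[3], 1e-3)
        std = np.array([2 * self.wp * h, 2 * self.wp * h, 1e-2, 2 * self.wp * h,
                        10 * self.wv * h, 10 * self.wv * h, 1e-5, 10 * self.wv * h])
        return KalmanState(mean, np.diag(std ** 2))

    def _process_noise(self, h):
        std = np.array([self.wp * h, self.wp * h, 1e-2, self.wp * h,
                        self.wv * h, self.wv * h, 1e-5, self.wv * h])
        return np.diag(std ** 2)

    def _measurement_noise(self, h):
        std = np.array([self.wp * h, self.wp * h, 1e-1, self.wp * h])
        return np.diag(std ** 2)

    def predict(self, s: KalmanState) -> KalmanState:
        h = max(s.mean[3], 1e-3)
        mean = self.F @ s.mean
        cov = self.F @ s.cov @ self.F.T + self._process_noise(h)
        return KalmanState(mean, cov)

    def project(self, s: KalmanState):
        h = max(s.mean[3], 1e-3)
        mean = self.H @ s.mean
        cov = self.H @ s.cov @ self.H.T + self._measurement_noise(h)
        return mean, cov

    def update(self, s: KalmanState, measurement: np.ndarray) -> KalmanState:
        pm, pc = self.project(s)
        chol = scipy.linalg.cho_factor(pc, lower=True)
        gain = scipy.linalg.cho_solve(chol, (s.cov @ self.H.T).T).T
        innovation = np.asarray(measurement, dtype=np.float64) - pm
        mean = s.mean + gain @ innovation
        cov = s.cov - gain @ pc @ gain.T
        mean[3] = max(mean[3], 1e-3)          # keep height positive
        cov = 0.5 * (cov + cov.T)             # enforce symmetry
        return KalmanState(mean, cov)

    def gating_distance(self, s: KalmanState, measurements: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of measurements to the projected state."""
        pm, pc = self.project(s)
        chol = scipy.linalg.cholesky(pc, lower=True)
        d = np.atleast_2d(measurements) - pm
        z = scipy.linalg.solve_triangular(chol, d.T, lower=True)
        return (z * z).sum(axis=0)


class TrackStatus(Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


def _xyxy_to_cxcyah(box):
    x1, y1, x2, y2 = box
    w, h = x2 - x1, y2 - y1
    return np.array([(x1 + x2) / 2, (y1 + y2) / 2, w / max(h, 1e-6), h])


def _cxcyah_to_xyxy(m):
    cx, cy, a, h = m[:4]
    w = a * h
    return np.array([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])


@dataclass
class Track:
    id: int
    state: KalmanState
    status: TrackStatus = TrackStatus.TENTATIVE
    hits: int = 1
    age: int = 1
    time_since_update: int = 0
    feature: np.ndarray | None = None
    score: float = 0.0
    dup_overlap: int = 0        # consecutive unmatched frames spent overlapping
                                # a freshly updated confirmed track

    @property
    def box(self) -> np.ndarray:
        return _cxcyah_to_xyxy(self.state.mean)


def histogram_embedding(frame: np.ndarray, box: np.ndarray,
                        bins: int = 8) -> np.ndarray | None:
    """8x8x8 RGB histogram of the box crop, L2-normalized."""
    h, w = frame.shape[:2]
    x1, y1, x2, y2 = (int(np.clip(box[0], 0, w)), int(np.clip(box[1], 0, h)),
                      int(np.ceil(np.clip(box[2], 0, w))),
                      int(np.ceil(np.clip(box[3], 0, h))))
    if x2 <= x1 or y2 <= y1:
        return None
    crop = frame[y1:y2, x1:x2].reshape(-1, 3)
    hist, _ = np.histogramdd(crop, bins=(bins,) * 3,
                             range=((0, 256),) * 3)
    v = hist.reshape(-1)
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - a @ b / (na * nb))


def associate(tracks, dets: BoxSet, kf: KalmanFilter,
              features: list | None = None, appearance_weight: float = 0.2,
              iou_thresh: float = 0.3, gate: float = GATE_CHI2_99_DF4,
              max_age: int = 30):
    """Cascade association.  Returns (matches, unmatched_track_idx,
    unmatched_det_idx) with matches as (track_idx, det_idx) pairs."""
    n_dets = len(dets)
    unmatched_dets = list(range(n_dets))
    matches = []
    if not tracks or n_dets == 0:
        return matches, list(range(len(tracks))), unmatched_dets

    measurements = np.array([_xyxy_to_cxcyah(b) for b in dets.boxes]) \
        if n_dets else np.zeros((0, 4))
    confirmed = [i for i, t in enumerate(tracks) if t.status is TrackStatus.CONFIRMED]
    others = [i for i, t in enumerate(tracks) if t.status is not TrackStatus.CONFIRMED]

    # cascade over time_since_update depth: freshest tracks match first
    for depth in range(1, max_age + 2):
        cohort = [i for i in confirmed if tracks[i].time_since_update == depth]
        if not cohort or not unmatched_dets:
            continue
        cost = np.zeros((len(cohort), len(unmatched_dets)))
        for r, ti in enumerate(cohort):
            maha = kf.gating_distance(tracks[ti].state,
                                      measurements[unmatched_dets])
            row = maha / gate
            if features is not None and tracks[ti].feature is not None:
                for c, di in enumerate(unmatched_dets):
                    fd = (1.0 if features[di] is None
                          else _cosine_distance(tracks[ti].feature, features[di]))
                    row[c] = (1 - appearance_weight) * row[c] \
                        + appearance_weight * fd
            row[maha > gate] = 1e6
            cost[r] = row
        rows, cols = linear_sum_assignment(cost)
        matched_dets = []
        for r, c in zip(rows, cols):
            if cost[r, c] >= 1e6:
                continue
            matches.append((cohort[r], unmatched_dets[c]))
            matched_dets.append(unmatched_dets[c])
        unmatched_dets = [d for d in unmatched_dets if d not in matched_dets]

    matched_tracks = {m[0] for m in matches}
    # IoU association for tentative tracks and unmatched confirmed ones
    leftovers = others + [i for i in confirmed
                          if i not in matched_tracks
                          and tracks[i].time_since_update == 1]
    if leftovers and unmatched_dets:
        track_boxes = np.array([tracks[i].box for i in leftovers])
        ious = iou_matrix(track_boxes, dets.boxes[unmatched_dets])
        cost = 1.0 - ious
        cost[ious < iou_thresh] = 1e6
        rows, cols = linear_sum_assignment(cost)
        matched_dets = []
        for r, c in zip(rows, cols):
            if cost[r, c] >= 1e6:
                continue
            matches.append((leftovers[r], unmatched_dets[c]))
            matched_dets.append(unmatched_dets[c])
        unmatched_dets = [d for d in unmatched_dets if d not in matched_dets]

    matched_tracks = {m[0] for m in matches}
    unmatched_tracks = [i for i in range(len(tracks)) if i not in matched_tracks]
    return matches, unmatched_tracks, unmatched_dets


class Tracker:
    """Per-video tracker orchestrating predict / associate / update."""

    def __init__(self, max_age: int = 30, n_init: int = 3,
                 appearance_weight: float = 0.2, iou_thresh: float = 0.3,
                 gate: float = GATE_CHI2_99_DF4, embed_fn=histogram_embedding,
                 feature_momentum: float = 0.9, dup_iou: float = 0.45,
                 dup_patience: int = 3):
        self.kf = KalmanFilter()
        self.max_age = max_age
        self.n_init = n_init
        self.appearance_weight = appearance_weight
        self.iou_thresh = iou_thresh
        self.gate = gate
        self.embed_fn = embed_fn
        self.feature_momentum = feature_momentum
        self.dup_iou = dup_iou
        self.dup_patience = dup_patience
        self.tracks: list[Track] = []
        self._next_id = 1

    def _suppress_duplicates(self):
        """Retire confirmed tracks that coast for ``dup_patience``
        consecutive frames while overlapping a freshly updated confirmed
        track: two confirmed tracks pinned to one target alternate in
        stealing its detections and end up double-counting it."""
        fresh = [t for t in self.tracks
                 if t.status is TrackStatus.CONFIRMED and t.time_since_update == 0]
        for t in self.tracks:
            if t.status is not TrackStatus.CONFIRMED or t.time_since_update == 0:
                t.dup_overlap = 0
                continue
            box = t.box[None]
            if fresh and any(iou_matrix(box, s.box[None])[0, 0] > self.dup_iou
                             for s in fresh):
                t.dup_overlap += 1
                if t.dup_overlap >= self.dup_patience:
                    t.status = TrackStatus.DELETED
            else:
                t.dup_overlap = 0

    def step(self, dets: BoxSet, frame_index: int,
             frame: np.ndarray | None = None) -> list[Track]:
        """Advance one frame; returns currently confirmed tracks."""
        for t in self.tracks:
            t.state = self.kf.predict(t.state)
            t.age += 1
            t.time_since_update += 1

        features = None
        if frame is not None and self.embed_fn is not None and len(dets):
            features = [self.embed_fn(frame, b) for b in dets.boxes]

        matches, unmatched_tracks, unmatched_dets = associate(
            self.tracks, dets, self.kf, features, self.appearance_weight,
            self.iou_thresh, self.gate, self.max_age)

        for ti, di in matches:
            t = self.tracks[ti]
            t.state = self.kf.update(t.state, _xyxy_to_cxcyah(dets.boxes[di]))
            t.hits += 1
            t.time_since_update = 0
            t.score = float(dets.scores[di])
            if features is not None and features[di] is not None:
                if t.feature is None:
                    t.feature = features[di]
                else:
                    a = self.feature_momentum
                    t.feature = a * t.feature + (1 - a) * features[di]
            if t.status is TrackStatus.TENTATIVE and t.hits >= self.n_init:
                t.status = TrackStatus.CONFIRMED

        for ti in unmatched_tracks:
            t = self.tracks[ti]
            if t.status is TrackStatus.TENTATIVE:
                t.status = TrackStatus.DELETED
            elif t.time_since_update > self.max_age:
                t.status = TrackStatus.DELETED

        for di in unmatched_dets:
            state = self.kf.initiate(_xyxy_to_cxcyah(dets.boxes[di]))
            self.tracks.append(Track(self._next_id, state,
                                     feature=None if features is None
                                     else features[di],
                                     score=float(dets.scores[di])))
            self._next_id += 1

        self._suppress_duplicates()
        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.DELETED]
        return [t for t in self.tracks
                if t.status is TrackStatus.CONFIRMED and t.time_since_update == 0]
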