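"""Line-crossing counting over track streams (the Streak rule).

The head-box center is the positional reference.  Each frame, every
track's signed side of the counting line is compared with its previous
side; a strict sign flip in the configured direction increments the tally
once per track id.  A center exactly on the line keeps its previous side,
so boundary jitter cannot double-count.  Tracks first seen beyond the
line are never counted (no inferred pre-history).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CountLine", "CountState", "head_center", "update_count", "LineCounter"]


@dataclass(frozen=True)
class CountLine:
    """Oriented line from p1 to p2; the positive side is to its left when
    looking from p1 to p2.  For a horizontal line stored left-to-right the
    positive side is below, so a negative-to-positive flip is a downward
    crossing."""

    p1: tuple
    p2: tuple
    direction: str = "down"              # "down", "up" or "both"

    def __post_init__(self):
        if tuple(self.p1) == tuple(self.p2):
            raise ValueError("line endpoints must be distinct")
        if self.direction not in ("down", "up", "both"):
            raise ValueError(f"direction must be down/up/both, got {self.direction}")

    @classmethod
    def horizontal(cls, y: float, width: float, direction: str = "down"):
        return cls((0.0, float(y)), (float(width), float(y)), direction)

    def side(self, point) -> int:
        (x1, y1), (x2, y2) = self.p1, self.p2
        z = (x2 - x1) * (point[1] - y1) - (y2 - y1) * (point[0] - x1)
        return int(np.sign(z))


@dataclass
class CountState:
    total: int = 0
    last_side: dict = field(default_factory=dict)     # track id -> -1/0/+1
    counted: dict = field(default_factory=dict)       # direction -> set of ids
    events: list = field(default_factory=list)        # (frame, id, direction)

    def counted_ids(self, direction: str):
        return self.counted.setdefault(direction, set())


def head_center(box) -> tuple:
    """Center of an xyxy box."""
    x1, y1, x2, y2 = box
    return ((x1 + x2) / 2.0, (y1 + y2) / 2.0)


def update_count(tracks, line: CountLine, state: CountState,
                 frame_index: int | None = None) -> CountState:
    """Advance the count with the current frame's confirmed tracks.

    ``tracks`` is any iterable of objects with ``id`` and ``box``
    attributes (or (id, box) pairs)."""
    for t in tracks:
        tid, box = (t.id, t.box) if hasattr(t, "id") else (t[0], t[1])
        side = line.side(head_center(box))
        prev = state.last_side.get(tid)
        if side == 0:
            continue                       # on the line: keep previous side
        if prev is not None and prev != 0 and side != prev:
            flip = "down" if (prev < 0 and side > 0) else "up"
            wanted = (line.direction == "both") or (line.direction == flip)
            if wanted and tid not in state.counted_ids(flip):
                state.total += 1
                state.counted_ids(flip).add(tid)
                state.events.append((frame_index, tid, flip))
        state.last_side[tid] = side
    return state


def annotate_frame(frame: np.ndarray, line: CountLine, total: int,
                   tracks=()) -> np.ndarray:
    """Overlay the counting line, the running total and track boxes on an
    RGB frame (returns a new array)."""
    from PIL import Image, ImageDraw

    img = Image.fromarray(np.ascontiguousarray(frame))
    draw = ImageDraw.Draw(img)
    draw.line([tuple(map(float, line.p1)), tuple(map(float, line.p2))],
              fill=(220, 30, 30), width=3)
    for t in tracks:
        tid, box = (t.id, t.box) if hasattr(t, "id") else (t[0], t[1])
        draw.rectangle([float(box[0]), float(box[1]),
                        float(box[2]), float(box[3])],
                       outline=(40, 220, 40), width=2)
        draw.text((float(box[0]), max(float(box[1]) - 12, 0)), str(tid),
                  fill=(40, 220, 40))
    draw.text((8, 8), f"count: {total}", fill=(220, 30, 30))
    return np.asarray(img)


class LineCounter:
    """Stateful wrapper pairing a CountLine with its CountState."""

    def __init__(self, line: CountLine):
        self.line = line
        self.state = CountState()

    def update(self, tracks, frame_index: int | None = None) -> int:
        update_count(tracks, self.line, self.state, frame_index)
        return self.state.total

    @property
    def total(self) -> int:
        return self.state.total

    def report(self) -> dict:
        return {
            "total": self.state.total,
            "per_track_events": [
                {"frame": f, "track_id": tid, "direction": d}
                for f, tid, d in self.state.events
            ],
        }
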