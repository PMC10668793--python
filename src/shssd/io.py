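"""Dataset formats and preprocessing.

Boxes are kept 0-based half-open ``[xmin, xmax) x [ymin, ymax)`` internally;
PASCAL-VOC's 1-based inclusive corners are converted on read and write so
that round-trips are lossless.  Preprocessing letterboxes to a square
canvas: the longest side is scaled to the target size, the remainder is
padded symmetrically with the (114, 114, 114) fill.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image

__all__ = [
    "ValidationError", "AnnotatedImage", "PreprocessedSample",
    "read_voc_xml", "write_voc_xml", "letterbox", "unletterbox_boxes",
    "augment", "read_image", "write_image", "iter_frames",
    "read_mot_csv", "write_mot_csv",
]

FILL = (114, 114, 114)
DEFAULT_CLASS = "sheep"


class ValidationError(ValueError):
    """Raised for inputs that parse but violate an invariant."""


@dataclass
class AnnotatedImage:
    """RGB image plus half-open pixel boxes and their class names."""

    image: np.ndarray | None
    boxes: np.ndarray
    labels: list
    source_path: str = ""

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        if len(self.boxes) != len(self.labels):
            raise ValidationError("boxes and labels must have equal length")
        if len(self.boxes):
            if (self.boxes[:, 2] <= self.boxes[:, 0]).any() or \
               (self.boxes[:, 3] <= self.boxes[:, 1]).any():
                raise ValidationError(f"degenerate box in {self.source_path or 'input'}")

    @property
    def size(self):
        """(W, H) of the image."""
        h, w = self.image.shape[:2]
        return w, h


@dataclass
class PreprocessedSample:
    """Letterboxed image with boxes mapped into the square canvas."""

    image: np.ndarray               # (S, S, 3) float32 in [0, 255]
    boxes: np.ndarray
    labels: list
    scale: float
    pad: tuple                      # (pad_x, pad_y)
    orig_size: tuple                # (W, H)


def read_voc_xml(path, class_filter: str | None = DEFAULT_CLASS,
                 load_image: bool = False) -> AnnotatedImage:
    """Parse one PASCAL-VOC annotation file.

    Only objects whose ``name`` equals ``class_filter`` are kept (pass
    ``None`` to keep everything).  Coordinates are converted from VOC's
    1-based inclusive corners to 0-based half-open."""
    path = os.fspath(path)
    try:
        tree = etree.parse(path)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ValidationError(f"malformed VOC XML {path!r}: {exc}") from exc
    root = tree.getroot()
    boxes, labels = [], []
    for obj in root.iter("object"):
        name = obj.findtext("name", "")
        if class_filter is not None and name != class_filter:
            continue
        bb = obj.find("bndbox")
        xmin = float(bb.findtext("xmin"))
        ymin = float(bb.findtext("ymin"))
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        if xmax <= xmin or ymax <= ymin:
            raise ValidationError(
                f"{path!r}: box ({xmin},{ymin},{xmax},{ymax}) has nonpositive extent")
        boxes.append([xmin - 1.0, ymin - 1.0, xmax, ymax])
        labels.append(name)
    image = None
    img_file = root.findtext("filename")
    if load_image and img_file:
        image = read_image(Path(path).parent / img_file)
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    return AnnotatedImage(image, boxes, labels, source_path=path)


def write_voc_xml(path, ann: AnnotatedImage, image_size: tuple | None = None,
                  filename: str | None = None):
    """Write an annotation back to VOC XML (inverse of :func:`read_voc_xml`)."""
    if image_size is None:
        image_size = ann.size
    w, h = image_size
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = filename or Path(
        ann.source_path or "frame.png").name
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(int(w))
    etree.SubElement(size, "height").text = str(int(h))
    etree.SubElement(size, "depth").text = "3"
    for box, label in zip(ann.boxes, ann.labels):
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = str(label)
        etree.SubElement(obj, "difficult").text = "0"
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = str(int(round(box[0] + 1)))
        etree.SubElement(bb, "ymin").text = str(int(round(box[1] + 1)))
        etree.SubElement(bb, "xmax").text = str(int(round(box[2])))
        etree.SubElement(bb, "ymax").text = str(int(round(box[3])))
    etree.ElementTree(root).write(os.fspath(path), pretty_print=True)


def letterbox(ann: AnnotatedImage, size: int = 640,
              fill: tuple = FILL) -> PreprocessedSample:
    """Aspect-preserving resize onto a ``size x size`` canvas."""
    img = ann.image
    if img is None or img.size == 0:
        raise ValidationError("letterbox requires a non-empty image")
    h, w = img.shape[:2]
    if h == 0 or w == 0:
        raise ValidationError("zero-area image")
    scale = size / max(h, w)
    nw, nh = int(round(w * scale)), int(round(h * scale))
    if (nw, nh) != (w, h):
        resized = np.asarray(
            Image.fromarray(img.astype(np.uint8)).resize((nw, nh), Image.BILINEAR))
    else:
        resized = img
    canvas = np.empty((size, size, 3), dtype=np.float32)
    canvas[...] = np.asarray(fill, dtype=np.float32)
    pad_x, pad_y = (size - nw) // 2, (size - nh) // 2
    canvas[pad_y : pad_y + nh, pad_x : pad_x + nw] = resized
    boxes = ann.boxes.copy()
    if len(boxes):
        boxes[:, 0::2] = boxes[:, 0::2] * scale + pad_x
        boxes[:, 1::2] = boxes[:, 1::2] * scale + pad_y
    return PreprocessedSample(canvas, boxes, list(ann.labels), scale,
                              (pad_x, pad_y), (w, h))


def unletterbox_boxes(boxes: np.ndarray, sample: PreprocessedSample) -> np.ndarray:
    """Map boxes from the letterboxed canvas back to original pixels."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4).copy()
    boxes[:, 0::2] = (boxes[:, 0::2] - sample.pad[0]) / sample.scale
    boxes[:, 1::2] = (boxes[:, 1::2] - sample.pad[1]) / sample.scale
    w, h = sample.orig_size
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
    return boxes


def _hsv_jitter(img: np.ndarray, rng: np.random.Generator,
                gains=(0.1, 0.3, 0.3)) -> np.ndarray:
    from skimage.color import hsv2rgb, rgb2hsv

    hsv = rgb2hsv(np.clip(img, 0, 255).astype(np.uint8))
    g = 1.0 + rng.uniform(-1, 1, size=3) * np.asarray(gains)
    hsv[..., 0] = (hsv[..., 0] * g[0]) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * g[1], 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * g[2], 0, 1)
    return (hsv2rgb(hsv) * 255.0).astype(np.float32)


def augment(sample: PreprocessedSample, rng: np.random.Generator,
            flip_prob: float = 0.5, crop_area: tuple = (0.6, 1.0),
            max_retries: int = 10) -> PreprocessedSample:
    """Training-time augmentation: horizontal flip, random scale-crop (boxes
    kept when their center stays inside, re-clipped otherwise), HSV jitter.
    Deterministic for a given generator state."""
    size = sample.image.shape[0]
    img = sample.image
    boxes = sample.boxes.copy()
    labels = list(sample.labels)

    if rng.random() < flip_prob:
        img = img[:, ::-1].copy()
        if len(boxes):
            x1 = size - boxes[:, 2]
            x2 = size - boxes[:, 0]
            boxes[:, 0], boxes[:, 2] = x1, x2

    for _ in range(max_retries):
        frac = rng.uniform(*crop_area)
        side = int(round(size * np.sqrt(frac)))
        x0 = int(rng.integers(0, size - side + 1))
        y0 = int(rng.integers(0, size - side + 1))
        if len(boxes) == 0:
            break
        cx = 0.5 * (boxes[:, 0] + boxes[:, 2])
        cy = 0.5 * (boxes[:, 1] + boxes[:, 3])
        keep = ((cx >= x0) & (cx < x0 + side)
                & (cy >= y0) & (cy < y0 + side))
        if keep.any():
            break
    else:                                   # retry cap: fall back to identity
        x0, y0, side, keep = 0, 0, size, np.ones(len(boxes), dtype=bool)

    if side != size or x0 or y0:
        crop = img[y0 : y0 + side, x0 : x0 + side]
        img = np.asarray(Image.fromarray(crop.astype(np.uint8))
                         .resize((size, size), Image.BILINEAR)).astype(np.float32)
        s = size / side
        if len(boxes):
            boxes = boxes[keep]
            labels = [l for l, k in zip(labels, keep) if k]
            boxes[:, 0::2] = np.clip((boxes[:, 0::2] - x0) * s, 0, size)
            boxes[:, 1::2] = np.clip((boxes[:, 1::2] - y0) * s, 0, size)
            ok = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
            boxes = boxes[ok]
            labels = [l for l, k in zip(labels, ok) if k]

    img = _hsv_jitter(img, rng)
    return PreprocessedSample(img, boxes, labels, sample.scale, sample.pad,
                              sample.orig_size)


# ---------------------------------------------------------------------------
# images / frames / detection streams


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(os.fspath(path)).convert("RGB"))


def write_image(path, img: np.ndarray):
    Image.fromarray(np.clip(img, 0, 255).astype(np.uint8)).save(os.fspath(path))


def iter_frames(source):
    """Yield (frame_index, RGB array) with a monotone index.

    ``source`` is a directory of image files (sorted by name) or a single
    movie file readable by imageio."""
    src = Path(source)
    if src.is_dir():
        files = sorted(p for p in src.iterdir()
                       if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".bmp"})
        for i, f in enumerate(files):
            yield i, read_image(f)
    else:
        import imageio.v3 as iio

        for i, frame in enumerate(iio.imiter(os.fspath(src))):
            yield i, np.asarray(frame)[..., :3]


def write_mot_csv(path, rows):
    """rows: iterable of (frame, id, x, y, w, h, score)."""
    with open(os.fspath(path), "w") as fh:
        for frame, tid, x, y, w, h, score in rows:
            fh.write(f"{int(frame)},{int(tid)},{x:.2f},{y:.2f},{w:.2f},{h:.2f},"
                     f"{score:.4f},-1,-1,-1\n")


def read_mot_csv(path):
    """Return dict frame -> list of (id, xyxy box, score)."""
    frames: dict[int, list] = {}
    with open(os.fspath(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise ValidationError(f"bad MOT line: {line!r}")
            frame, tid = int(float(parts[0])), int(float(parts[1]))
            x, y, w, h, score = (float(v) for v in parts[2:7])
            frames.setdefault(frame, []).append(
                (tid, np.array([x, y, x + w, y + h]), score))
    return frames
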