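"""Region-of-interest ingestion and a naive phantom detector.

The pipeline consumes three boxes per leg — femoral head, knee, ankle —
normally produced by an external object detector whose output is written in
the darknet text dialect (one row per box: ``class cx cy w h [confidence]``
with center/size normalized to [0, 1]).  This module parses that dialect,
groups boxes into per-leg triples, and also provides
:func:`phantom_detector`, a simple intensity-profile detector that locates
the three structures on synthetic leg phantoms so the full pipeline can run
without any trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .exceptions import DetectionFailureError
from .utils import as_float_gray

__all__ = [
    "BoundingBox",
    "CLASS_LABELS",
    "read_darknet_boxes",
    "write_darknet_boxes",
    "LegBoxSet",
    "select_leg_boxes",
    "phantom_detector",
]

CLASS_LABELS = ("femoral_head", "knee", "ankle")


@dataclass(frozen=True)
class BoundingBox:
    """An axis-aligned detection box in pixel corner coordinates."""

    class_label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence outside [0, 1]: {self.confidence}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def clipped(self, image_width: float, image_height: float) -> "BoundingBox":
        return replace(
            self,
            x_min=max(0.0, self.x_min),
            y_min=max(0.0, self.y_min),
            x_max=min(float(image_width), self.x_max),
            y_max=min(float(image_height), self.y_max),
        )

    def translated(self, dx: float, dy: float) -> "BoundingBox":
        return replace(
            self,
            x_min=self.x_min + dx,
            x_max=self.x_max + dx,
            y_min=self.y_min + dy,
            y_max=self.y_max + dy,
        )

    def iou(self, other: "BoundingBox") -> float:
        ix = max(0.0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0.0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        union = self.width * self.height + other.width * other.height - inter
        return inter / union if union > 0 else 0.0


def read_darknet_boxes(
    path,
    image_width: int,
    image_height: int,
    class_map: Mapping[int, str],
) -> list[BoundingBox]:
    """Parse a darknet-dialect box file into pixel-coordinate boxes.

    Each non-empty row is ``class cx cy w h`` (optionally followed by a
    confidence), all geometry normalized to [0, 1].  Boxes are denormalized,
    clipped to the image, and class ids mapped through ``class_map``.
    """
    boxes: list[BoundingBox] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
            try:
                cls = int(parts[0])
                cx, cy, w, h = (float(v) for v in parts[1:5])
                conf = float(parts[5]) if len(parts) == 6 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}") from exc
            for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(
                        f"{path}:{lineno}: normalized {name}={v} outside [0, 1]"
                    )
            if cls not in class_map:
                raise ValueError(f"{path}:{lineno}: unknown class id {cls}")
            box = BoundingBox(
                class_label=class_map[cls],
                x_min=(cx - w / 2) * image_width,
                y_min=(cy - h / 2) * image_height,
                x_max=(cx + w / 2) * image_width,
                y_max=(cy + h / 2) * image_height,
                confidence=conf,
            ).clipped(image_width, image_height)
            boxes.append(box)
    return boxes


def write_darknet_boxes(
    boxes: Iterable[BoundingBox],
    path,
    image_width: int,
    image_height: int,
    class_ids: Mapping[str, int] | None = None,
) -> None:
    """Write boxes in the darknet dialect (inverse of :func:`read_darknet_boxes`)."""
    if class_ids is None:
        class_ids = {label: i for i, label in enumerate(CLASS_LABELS)}
    with open(path, "w") as fh:
        for b in boxes:
            cx, cy = b.center
            fh.write(
                f"{class_ids[b.class_label]} "
                f"{cx / image_width:.6f} {cy / image_height:.6f} "
                f"{b.width / image_width:.6f} {b.height / image_height:.6f} "
                f"{b.confidence:.6f}\n"
            )


class LegBoxSet(NamedTuple):
    """The three ROI boxes of one leg."""

    femoral_head: BoundingBox
    knee: BoundingBox
    ankle: BoundingBox


@dataclass
class LegSelection:
    """Per-leg box triples plus a report of incomplete sides."""

    complete: dict[str, LegBoxSet] = field(default_factory=dict)
    incomplete: dict[str, list[str]] = field(default_factory=dict)


def select_leg_boxes(boxes: Iterable[BoundingBox], image_width: int) -> LegSelection:
    """Group detector boxes into per-leg (image-side) triples.

    Boxes are partitioned into image-left / image-right by box center x
    relative to the image midline; within each side and class the
    highest-confidence box wins.  When at most one box of each class is
    present, the boxes are treated as one leg under the side name
    ``"single"``, which covers single-leg images whose boxes straddle the
    midline.  Sides missing a required class are reported as incomplete.
    """
    boxes = list(boxes)
    sel = LegSelection()
    if not boxes:
        return sel

    per_class_counts = {c: sum(b.class_label == c for b in boxes) for c in CLASS_LABELS}
    if max(per_class_counts.values(), default=0) <= 1:
        sides = {"single": boxes}
    else:
        sides = {"left": [], "right": []}
        for b in boxes:
            side = "left" if b.center[0] < image_width / 2 else "right"
            sides[side].append(b)
        sides = {s: bs for s, bs in sides.items() if bs}

    for side, side_boxes in sides.items():
        best: dict[str, BoundingBox] = {}
        for b in side_boxes:
            if b.class_label not in CLASS_LABELS:
                continue
            cur = best.get(b.class_label)
            if cur is None or b.confidence > cur.confidence:
                best[b.class_label] = b
        missing = [c for c in CLASS_LABELS if c not in best]
        if missing:
            sel.incomplete[side] = missing
        else:
            sel.complete[side] = LegBoxSet(
                best["femoral_head"], best["knee"], best["ankle"]
            )
    return sel


# ---------------------------------------------------------------------------
# naive phantom detector


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a 1-D boolean array as (start, stop) pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def _detect_one_leg(
    image: np.ndarray, col0: int, col1: int, threshold: float
) -> list[BoundingBox]:
    """Locate head / knee / ankle structures in one leg's column range."""
    h = image.shape[0]
    sub = image[:, col0:col1]
    bright = sub > threshold
    widths = bright.sum(axis=1).astype(float)

    def extent_box(rows: tuple[int, int], label: str, margin: float) -> BoundingBox:
        r0, r1 = rows
        cols = np.flatnonzero(bright[r0:r1].any(axis=0))
        return BoundingBox(
            label,
            x_min=col0 + cols[0] - margin,
            y_min=r0 - margin,
            x_max=col0 + cols[-1] + 1 + margin,
            y_max=r1 + margin,
        )

    boxes: list[BoundingBox] = []

    # femoral head: widest contiguous band in the top 40% of the leg
    top = slice(0, int(0.40 * h))
    wmax = widths[top].max() if widths[top].size else 0.0
    if wmax < 4:
        raise DetectionFailureError("no bright structure in head region", stage="roi")
    head_rows = [r for r in _runs(widths[: top.stop] > 0.6 * wmax) if r[1] - r[0] >= 5]
    if not head_rows:
        raise DetectionFailureError("no femoral head profile peak", stage="roi")
    head_rows = max(head_rows, key=lambda r: r[1] - r[0])
    # the widest row spans the disk diameter; size the box from it so the
    # clipped top/bottom caps of the disk stay inside
    yc = 0.5 * (head_rows[0] + head_rows[1])
    half = wmax / 2 + 4
    cols = np.flatnonzero(bright[head_rows[0] : head_rows[1]].any(axis=0))
    xc = col0 + 0.5 * (cols[0] + cols[-1])
    boxes.append(
        BoundingBox("femoral_head", xc - half, yc - half, xc + half, yc + half)
    )

    # knee: widest band in the middle of the leg (tibial plateau region)
    mid = slice(int(0.35 * h), int(0.78 * h))
    wmid = widths[mid]
    if wmid.max() < 4:
        raise DetectionFailureError("no bright structure in knee region", stage="roi")
    knee_mask = np.zeros(h, bool)
    knee_mask[mid] = wmid > 0.6 * wmid.max()
    knee_rows = [r for r in _runs(knee_mask) if r[1] - r[0] >= 8]
    if not knee_rows:
        raise DetectionFailureError("no knee profile peak", stage="roi")
    knee_rows = max(knee_rows, key=lambda r: r[1] - r[0])
    boxes.append(extent_box(knee_rows, "knee", margin=8))

    # ankle: two wide blocks (tibial plafond, talus) separated by the dark
    # joint band in the bottom 25% of the leg
    bot0 = int(0.75 * h)
    wbot = widths[bot0:]
    if wbot.max() < 4:
        raise DetectionFailureError("no bright structure in ankle region", stage="roi")
    wide = [r for r in _runs(wbot > 0.6 * wbot.max()) if r[1] - r[0] >= 4]
    if len(wide) < 2:
        raise DetectionFailureError(
            "tibiotalar band not found", stage="roi",
            diagnostics={"wide_runs": len(wide)},
        )
    wide = sorted(wide, key=lambda r: r[0])[-2:]
    rows = (bot0 + wide[0][0], bot0 + wide[1][1])
    boxes.append(extent_box(rows, "ankle", margin=6))

    hgt, wid = image.shape
    return [b.clipped(wid, hgt) for b in boxes]


def phantom_detector(image: np.ndarray) -> list[BoundingBox]:
    """Locate head/knee/ankle boxes on a synthetic leg phantom.

    Works by vertical intensity profiling of the thresholded image; splits
    the image into leg column clusters first so that side-by-side two-leg
    phantoms yield six boxes.  This is a stand-in detector for phantoms
    only — it assumes the stylized bright-bone-on-dark-field rendering.
    """
    img = as_float_gray(image)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-3:
        raise DetectionFailureError("blank image", stage="roi")
    threshold = lo + 0.5 * (hi - lo)
    colsum = (img > threshold).sum(axis=0)
    clusters = [c for c in _runs(colsum > 0) if c[1] - c[0] >= 10]
    if not clusters:
        raise DetectionFailureError("no bright columns", stage="roi")
    # merge clusters separated by < 40 px (within one leg)
    merged = [list(clusters[0])]
    for c0, c1 in clusters[1:]:
        if c0 - merged[-1][1] < 40:
            merged[-1][1] = c1
        else:
            merged.append([c0, c1])
    boxes: list[BoundingBox] = []
    for c0, c1 in merged:
        pad = 10
        boxes.extend(
            _detect_one_leg(
                img,
                max(0, c0 - pad),
                min(img.shape[1], c1 + pad),
                threshold,
            )
        )
    return boxes
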