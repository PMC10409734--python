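"""Circular Hough transform for femoral head center detection.

A circle with center ``(a, b)`` and radius ``r`` satisfies
``(x - a)^2 + (y - b)^2 = r^2`` for every border point ``(x, y)``.  The
accumulator counts, for every candidate center and radius, the edge pixels
whose distance to the center is within half a pixel of the radius; peaks of
the vote array are circle hypotheses.  The search is restricted to radii
proportional to the femoral-head bounding box, and among near-maximal peaks
the hypothesis whose supporting edge gradients point most directly at the
center is preferred (the classic gradient-direction peak criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters

from .exceptions import DetectionFailureError
from .geometry import Point
from .roi import BoundingBox
from .utils import as_float_gray, crop

__all__ = [
    "CircleHypothesis",
    "RadiusRange",
    "edge_map",
    "hough_accumulate",
    "femoral_head_center",
]

#: Membership tolerance of the circle equation, in pixels.
HALF_PIXEL = 0.5


@dataclass(frozen=True)
class CircleHypothesis:
    """One candidate circle: center (a, b), radius r, and its vote count."""

    a: float
    b: float
    r: float
    votes: int


@dataclass(frozen=True)
class RadiusRange:
    """Inclusive integer radius search range."""

    r_min: int
    r_max: int

    def __post_init__(self):
        if not (0 < self.r_min <= self.r_max):
            raise ValueError(f"invalid radius range [{self.r_min}, {self.r_max}]")

    @staticmethod
    def from_bbox(bbox: BoundingBox, c_lo: float = 0.5, c_hi: float = 1.0) -> "RadiusRange":
        """Radius range proportional to half the shorter bounding-box side."""
        half = min(bbox.width, bbox.height) / 2.0
        r_min = max(1, int(round(c_lo * half)))
        r_max = max(r_min, int(round(c_hi * half)))
        return RadiusRange(r_min, r_max)

    def radii(self, step: int = 1) -> np.ndarray:
        return np.arange(self.r_min, self.r_max + 1, step, dtype=int)


def edge_map(
    roi_image: np.ndarray,
    sigma: float = 1.5,
    low_threshold: float | None = None,
    high_threshold: float | None = None,
) -> np.ndarray:
    """Canny edge mask of a grayscale ROI (empty mask on a constant image)."""
    img = as_float_gray(roi_image)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        return np.zeros_like(img, dtype=bool)
    return feature.canny(
        img, sigma=sigma, low_threshold=low_threshold, high_threshold=high_threshold
    )


def _annulus_offsets(r: int) -> np.ndarray:
    """Integer (dy, dx) offsets with | hypot - r | <= 1/2 pixel."""
    rng = np.arange(-r - 1, r + 2)
    dy, dx = np.meshgrid(rng, rng, indexing="ij")
    dist = np.hypot(dy, dx)
    keep = np.abs(dist - r) <= HALF_PIXEL
    return np.stack([dy[keep], dx[keep]], axis=1)


def vote_array(edges: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Hough accumulator of shape (len(radii), H, W).

    ``acc[k, b, a]`` is the number of edge pixels at distance
    ``radii[k] +- 1/2`` from center ``(a, b)`` — identical, by construction,
    to exhaustively testing the circle equation for every edge pixel.
    """
    edges = np.asarray(edges, dtype=bool)
    h, w = edges.shape
    ys, xs = np.nonzero(edges)
    acc = np.zeros((len(radii), h, w), dtype=np.int64)
    for k, r in enumerate(radii):
        off = _annulus_offsets(int(r))
        cy = ys[:, None] + off[None, :, 0]
        cx = xs[:, None] + off[None, :, 1]
        ok = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < w)
        np.add.at(acc[k], (cy[ok], cx[ok]), 1)
    return acc


def hough_accumulate(
    edges: np.ndarray,
    radii: RadiusRange | np.ndarray,
    step: int = 1,
    min_votes: int = 2,
) -> tuple[list[CircleHypothesis], np.ndarray, np.ndarray]:
    """Accumulate circle votes and extract local-maximum hypotheses.

    Returns ``(hypotheses, accumulator, radii)`` with hypotheses sorted by
    vote count descending.  An empty edge mask yields no hypotheses.
    """
    if isinstance(radii, RadiusRange):
        radii = radii.radii(step)
    radii = np.asarray(radii, dtype=int)
    edges = np.asarray(edges, dtype=bool)
    acc = vote_array(edges, radii)
    if not edges.any() or acc.max() == 0:
        return [], acc, radii
    local_max = acc == ndimage.maximum_filter(acc, size=3, mode="constant")
    ks, bs, as_ = np.nonzero(local_max & (acc >= min_votes))
    votes = acc[ks, bs, as_]
    order = np.argsort(-votes, kind="stable")
    hyps = [
        CircleHypothesis(a=float(as_[i]), b=float(bs[i]), r=float(radii[ks[i]]), votes=int(votes[i]))
        for i in order
    ]
    return hyps, acc, radii


def _gradient_alignment(
    roi: np.ndarray, edges: np.ndarray, hyp: CircleHypothesis
) -> float:
    """Mean |cos| between edge gradients and the direction to the center.

    Edge pixels supporting the hypothesis should have their maximum
    gray-level gradient pointing along the radius; this scores how well
    they do, ignoring polarity (bright or dark disk).
    """
    ys, xs = np.nonzero(edges)
    dist = np.hypot(ys - hyp.b, xs - hyp.a)
    sup = np.abs(dist - hyp.r) <= HALF_PIXEL
    if not sup.any():
        return 0.0
    gy = ndimage.sobel(roi, axis=0)
    gx = ndimage.sobel(roi, axis=1)
    gvx, gvy = gx[ys[sup], xs[sup]], gy[ys[sup], xs[sup]]
    rx, ry = hyp.a - xs[sup], hyp.b - ys[sup]
    gn = np.hypot(gvx, gvy)
    rn = np.hypot(rx, ry)
    ok = (gn > 0) & (rn > 0)
    if not ok.any():
        return 0.0
    cosang = (gvx * rx + gvy * ry)[ok] / (gn * rn)[ok]
    return float(np.mean(np.abs(cosang)))


def _subpixel_center(acc_r: np.ndarray, b: int, a: int) -> tuple[float, float]:
    """Vote-weighted centroid of the 3x3 accumulator patch around a peak."""
    h, w = acc_r.shape
    y0, y1 = max(0, b - 1), min(h, b + 2)
    x0, x1 = max(0, a - 1), min(w, a + 2)
    patch = acc_r[y0:y1, x0:x1].astype(float)
    total = patch.sum()
    if total == 0:
        return float(a), float(b)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    return float((xs * patch).sum() / total), float((ys * patch).sum() / total)


def femoral_head_center(
    image: np.ndarray,
    bbox: BoundingBox,
    c_lo: float = 0.5,
    c_hi: float = 1.0,
    radius_step: int = 1,
    sigma: float = 1.5,
    low_threshold: float | None = None,
    high_threshold: float | None = None,
    vote_floor: float = 0.3,
    peak_tolerance: float = 0.05,
) -> tuple[Point, float]:
    """Detect the femoral head center inside its bounding box.

    Runs Canny edges and the circular Hough accumulator with radii
    restricted to ``[c_lo, c_hi]`` times half the shorter box side, keeps
    hypotheses within ``peak_tolerance`` of the top vote count, selects by
    gradient alignment (ties: larger radius, then smaller y), and refines
    the center to sub-pixel precision from the accumulator neighborhood.

    Returns the center in full-image coordinates plus the radius.
    Raises :class:`DetectionFailureError` when no hypothesis reaches
    ``vote_floor`` times the circle perimeter.
    """
    img = as_float_gray(image)
    roi, (x0, y0) = crop(img, bbox.x_min, bbox.y_min, bbox.x_max, bbox.y_max)
    edges = edge_map(roi, sigma=sigma, low_threshold=low_threshold, high_threshold=high_threshold)
    rr = RadiusRange.from_bbox(bbox, c_lo=c_lo, c_hi=c_hi)
    hyps, acc, radii = hough_accumulate(edges, rr, step=radius_step)
    hyps = [h for h in hyps if h.votes >= vote_floor * 2 * np.pi * h.r]
    if not hyps:
        raise DetectionFailureError(
            "no circle hypothesis above the vote floor",
            stage="femoral_head",
            diagnostics={
                "n_edge_pixels": int(edges.sum()),
                "max_votes": int(acc.max()) if acc.size else 0,
                "radius_range": (rr.r_min, rr.r_max),
            },
        )
    top = hyps[0].votes
    candidates = [h for h in hyps if h.votes >= (1 - peak_tolerance) * top]
    smooth = ndimage.gaussian_filter(roi, sigma)
    best = max(
        candidates,
        key=lambda hy: (_gradient_alignment(smooth, edges, hy), hy.r, -hy.b),
    )
    k = int(np.nonzero(radii == int(best.r))[0][0])
    ax, by = _subpixel_center(acc[k], int(best.b), int(best.a))
    return Point(x0 + ax, y0 + by), float(best.r)
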