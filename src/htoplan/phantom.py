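"""Synthetic long-leg AP radiograph phantoms with exact ground truth.

A phantom emulates the structures every pipeline stage keys on: a bright
circular femoral head, femoral and tibial shafts, a tibial plateau contour
through the inner and outer knee points, and a dark horizontal tibiotalar
joint band centered at the ankle.  The varus deformity is parameterized by
the desired Miniaci correction angle: the ankle center is *placed by
inverting the planning geometry*, so the stored ground-truth landmarks
reproduce the requested angle exactly and every detection stage can be
scored against exact truth.

Phantoms are deliberately stylized (disks, bands, polylines rather than
realistic bone texture); each stage detects exactly these primitives, which
keeps tests fast and the truth analytic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from skimage import draw

from . import geometry
from .geometry import Laterality, LegLandmarks, Point
from .roi import BoundingBox
from .shapes import LandmarkShape

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "solve_ankle_position",
    "knee_contour",
    "render",
    "compose_legs",
    "sample_specs",
    "default_angle_distribution",
]

MAX_ANGLE_DEG = 30.0
MARGIN = 5.0

#: rendering intensities (float image in [0, 1])
BACKGROUND = 0.08
BONE = 0.85
HEAD = 0.95
JOINT_SPACE = 0.02


@dataclass(frozen=True)
class PhantomSpec:
    """Parameterization of one synthetic leg radiograph."""

    width: int = 384
    height: int = 768
    laterality: Laterality = Laterality.RIGHT
    head_center: Point = Point(192.0, 80.0)
    head_radius: float = 28.0
    knee_y: float = 420.0
    knee_width: float = 90.0
    knee_center_x: float = 192.0
    angle_deg: float = 8.0
    femur_width: float = 14.0
    tibia_width: float = 16.0
    joint_band_height: float = 6.0
    talus_halfwidth: float = 28.0
    plateau_sag: float = 7.0
    side_depth: float = 28.0
    landmark_count: int = 59
    tibia_length: float = 280.0
    noise_sigma: float = 0.0
    salt_density: float = 0.0
    seed: int = 0

    @property
    def knee_outer(self) -> Point:
        """Lateral plateau edge."""
        sign = self.laterality.medial_sign
        return Point(self.knee_center_x - sign * self.knee_width / 2, self.knee_y)

    @property
    def knee_inner(self) -> Point:
        """Medial plateau edge."""
        sign = self.laterality.medial_sign
        return Point(self.knee_center_x + sign * self.knee_width / 2, self.knee_y)

    @property
    def ground_level_y(self) -> float:
        return self.knee_y + self.tibia_length

    def validate(self) -> None:
        if not 0.0 <= self.angle_deg <= MAX_ANGLE_DEG:
            raise ValueError(
                f"requested correction angle {self.angle_deg} outside [0, {MAX_ANGLE_DEG}]"
            )
        if self.landmark_count < 9:
            raise ValueError("landmark_count too small for a contour")
        hc = self.head_center
        for x, y in [
            (hc.x - self.head_radius, hc.y - self.head_radius),
            (hc.x + self.head_radius, hc.y + self.head_radius),
            (self.knee_outer.x, self.knee_y + self.side_depth),
            (self.knee_inner.x, self.knee_y + self.side_depth),
        ]:
            if not (MARGIN <= x <= self.width - MARGIN and MARGIN <= y <= self.height - MARGIN):
                raise ValueError(f"structure point ({x:.0f}, {y:.0f}) violates the image margin")
        if self.ground_level_y + self.joint_band_height / 2 + 30 > self.height - MARGIN:
            raise ValueError("ankle region extends past the bottom margin")


@dataclass(frozen=True)
class PhantomTruth:
    """Exact ground truth emitted with every rendered phantom."""

    landmarks: LegLandmarks
    boxes: dict[str, BoundingBox]
    angle_deg: float
    knee_shape: LandmarkShape

    def translated(self, dx: float, dy: float) -> "PhantomTruth":
        lm = self.landmarks
        moved = LegLandmarks(
            **{
                name: Point(getattr(lm, name).x + dx, getattr(lm, name).y + dy)
                for name in (
                    "femoral_head_center", "medial_plateau_edge", "lateral_plateau_edge",
                    "fujisawa_point", "talus_inner", "talus_outer", "ankle_center",
                    "hinge_point",
                )
            },
            laterality=lm.laterality,
        )
        return PhantomTruth(
            landmarks=moved,
            boxes={k: b.translated(dx, dy) for k, b in self.boxes.items()},
            angle_deg=self.angle_deg,
            knee_shape=self.knee_shape.translated(dx, dy),
        )

    def to_dict(self) -> dict:
        lm = self.landmarks
        return {
            "angle_deg": self.angle_deg,
            "laterality": lm.laterality.value,
            "landmarks": {
                name: list(getattr(lm, name))
                for name in (
                    "femoral_head_center", "medial_plateau_edge", "lateral_plateau_edge",
                    "fujisawa_point", "talus_inner", "talus_outer", "ankle_center",
                    "hinge_point",
                )
            },
            "boxes": {
                k: [b.x_min, b.y_min, b.x_max, b.y_max] for k, b in self.boxes.items()
            },
            "knee_shape": {
                "points": self.knee_shape.points.tolist(),
                "index_map": self.knee_shape.index_map,
            },
        }


def solve_ankle_position(
    head: Point,
    fujisawa: Point,
    hinge: Point,
    angle_deg: float,
    ground_level_y: float,
    laterality: Laterality | str = Laterality.RIGHT,
) -> Point:
    """Place the ankle center so the Miniaci angle equals ``angle_deg``.

    Inverts the planning construction: the correction axis is extended to
    the ground level (point G) and the ray hinge->G is rotated *medially*
    by the requested angle; the ankle center is the intersection of the
    rotated ray with the ground line.  A positive angle therefore yields a
    varus leg whose plan asks for a valgus-producing correction of exactly
    that magnitude.
    """
    if not 0.0 <= angle_deg <= MAX_ANGLE_DEG:
        raise ValueError(f"angle {angle_deg} outside [0, {MAX_ANGLE_DEG}] degrees")
    laterality = Laterality(laterality)
    g = geometry.ground_intersection(head, fujisawa, ground_level_y)
    hp = Point.of(hinge)
    vg = g.as_array() - hp.as_array()
    theta = math.radians(laterality.medial_sign * angle_deg)
    # inverse of the signed-angle convention: ankle ray = R(-theta) (G - HP)
    c, s = math.cos(-theta), math.sin(-theta)
    v = np.array([c * vg[0] - s * vg[1], s * vg[0] + c * vg[1]])
    if v[1] <= 0:
        raise ValueError("rotated ankle ray does not reach the ground level")
    t = (ground_level_y - hp.y) / v[1]
    return Point(hp.x + t * v[0], float(ground_level_y))


def knee_contour(
    outer: Point, inner: Point, n: int, sag: float, side_depth: float,
    laterality: Laterality | None = None,
) -> LandmarkShape:
    """Canonical knee landmark contour through the plateau edges.

    The contour runs up the outer tibial side, across the plateau arc (a
    shallow bulge of depth ``sag``), and down the inner side; the plateau
    endpoints are the characteristic outer and inner knee points, whose
    indices are recorded in the shape's index map.
    """
    n_side = max(3, int(round(0.2 * n)))
    n_top = n - 2 * n_side
    if n_top < 3:
        raise ValueError(f"landmark count {n} too small")
    pts = []
    for k in range(n_side):
        frac = 1.0 - k / n_side
        pts.append([outer.x, outer.y + side_depth * frac])
    t = np.linspace(0.0, 1.0, n_top)
    arc_x = outer.x + t * (inner.x - outer.x)
    arc_y = outer.y + t * (inner.y - outer.y) - 4.0 * sag * t * (1.0 - t)
    pts.extend(np.stack([arc_x, arc_y], axis=1).tolist())
    for k in range(1, n_side + 1):
        frac = k / n_side
        pts.append([inner.x, inner.y + side_depth * frac])
    index_map = {"outer": n_side, "inner": n_side + n_top - 1}
    return LandmarkShape(np.asarray(pts), index_map, laterality)


def _fill_polygon(img: np.ndarray, xs, ys, value: float) -> None:
    rr, cc = draw.polygon(np.asarray(ys), np.asarray(xs), shape=img.shape)
    img[rr, cc] = value


def _thick_line(img: np.ndarray, p0, p1, width: float, value: float) -> None:
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    n = np.hypot(*d)
    if n == 0:
        return
    perp = np.array([-d[1], d[0]]) / n * (width / 2)
    corners = [p0 + perp, p1 + perp, p1 - perp, p0 - perp]
    _fill_polygon(img, [c[0] for c in corners], [c[1] for c in corners], value)


def _truth(spec: PhantomSpec) -> PhantomTruth:
    outer, inner = spec.knee_outer, spec.knee_inner
    lat = spec.laterality
    medial, lateral = inner, outer
    fuji = geometry.fujisawa_point(medial, lateral)
    hinge = geometry.hinge_point(outer, inner, lat)
    ankle = solve_ankle_position(
        spec.head_center, fuji, hinge, spec.angle_deg, spec.ground_level_y, lat
    )
    sign = lat.medial_sign
    talus_inner = Point(ankle.x + sign * spec.talus_halfwidth, ankle.y)
    talus_outer = Point(ankle.x - sign * spec.talus_halfwidth, ankle.y)
    landmarks = LegLandmarks(
        femoral_head_center=spec.head_center,
        medial_plateau_edge=medial,
        lateral_plateau_edge=lateral,
        fujisawa_point=fuji,
        talus_inner=talus_inner,
        talus_outer=talus_outer,
        ankle_center=ankle,
        hinge_point=hinge,
        laterality=lat,
    )
    landmarks.validate()

    shape = knee_contour(outer, inner, spec.landmark_count, spec.plateau_sag, spec.side_depth, lat)
    hc, r = spec.head_center, spec.head_radius
    band = spec.joint_band_height
    boxes = {
        "femoral_head": BoundingBox(
            "femoral_head", hc.x - r - 6, hc.y - r - 6, hc.x + r + 6, hc.y + r + 6
        ),
        "knee": BoundingBox(
            "knee",
            min(outer.x, inner.x) - 12,
            spec.knee_y - spec.plateau_sag - 12,
            max(outer.x, inner.x) + 12,
            spec.knee_y + spec.side_depth + 12,
        ),
        "ankle": BoundingBox(
            "ankle",
            ankle.x - spec.talus_halfwidth - 12,
            ankle.y - band / 2 - 18 - 8,
            ankle.x + spec.talus_halfwidth + 12,
            ankle.y + band / 2 + 24 + 8,
        ),
    }
    boxes = {k: b.clipped(spec.width, spec.height) for k, b in boxes.items()}
    return PhantomTruth(landmarks=landmarks, boxes=boxes, angle_deg=spec.angle_deg, knee_shape=shape)


def render(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Rasterize a phantom and return the image with its exact truth.

    Rendering is deterministic: identical specs (including the seed of the
    noise model) yield bit-identical images.
    """
    spec.validate()
    truth = _truth(spec)
    lm = truth.landmarks
    img = np.full((spec.height, spec.width), BACKGROUND, dtype=float)

    outer, inner = spec.knee_outer, spec.knee_inner
    knee_mid = Point(0.5 * (outer.x + inner.x), 0.5 * (outer.y + inner.y))

    # femur shaft ends above the plateau, leaving a dark knee joint gap
    femur_end = Point(knee_mid.x, spec.knee_y - spec.plateau_sag - 12)
    _thick_line(img, spec.head_center, femur_end, spec.femur_width, BONE)
    rr, cc = draw.disk((lm.femoral_head_center.y, lm.femoral_head_center.x),
                       spec.head_radius, shape=img.shape)
    img[rr, cc] = HEAD

    # proximal tibia: region below the plateau contour
    contour = truth.knee_shape.points
    _fill_polygon(img, contour[:, 0], contour[:, 1], BONE)

    # tibial shaft down to the ankle
    ankle = lm.ankle_center
    band = spec.joint_band_height
    plafond_top = ankle.y - band / 2 - 18
    _thick_line(img, (knee_mid.x, spec.knee_y + spec.side_depth - 2),
                (ankle.x, plafond_top + 2), spec.tibia_width, BONE)

    # distal tibia (plafond) above the joint band, talus below it
    half = spec.talus_halfwidth
    _fill_polygon(
        img,
        [ankle.x - half, ankle.x + half, ankle.x + half, ankle.x - half],
        [plafond_top, plafond_top, ankle.y - band / 2, ankle.y - band / 2],
        BONE,
    )
    _fill_polygon(
        img,
        [ankle.x - half, ankle.x + half, ankle.x + half, ankle.x - half],
        [ankle.y + band / 2, ankle.y + band / 2, ankle.y + band / 2 + 24, ankle.y + band / 2 + 24],
        BONE,
    )
    # the dark tibiotalar joint band itself
    _fill_polygon(
        img,
        [ankle.x - half, ankle.x + half, ankle.x + half, ankle.x - half],
        [ankle.y - band / 2, ankle.y - band / 2, ankle.y + band / 2, ankle.y + band / 2],
        JOINT_SPACE,
    )

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    if spec.salt_density > 0:
        salt = rng.random(img.shape) < spec.salt_density
        img[salt] = 1.0
    return np.clip(img, 0.0, 1.0), truth


def compose_legs(spec_left_side: PhantomSpec, spec_right_side: PhantomSpec):
    """Render two phantoms side by side into one two-leg image.

    Returns ``(image, truths)`` with the second truth translated into the
    right half.  By AP convention the image-left leg is the patient's right
    leg and vice versa.
    """
    img_l, truth_l = render(spec_left_side)
    img_r, truth_r = render(spec_right_side)
    if img_l.shape[0] != img_r.shape[0]:
        raise ValueError("both phantoms must share the same height")
    image = np.concatenate([img_l, img_r], axis=1)
    return image, [truth_l, truth_r.translated(img_l.shape[1], 0.0)]


def default_angle_distribution():
    """Skew-normal angle distribution mimicking a clinical case mix.

    Centered in the 4-18 degree window where an osteotomy is typically
    indicated, with a right tail for severe varus cases.
    """
    from scipy import stats

    return stats.skewnorm(a=4.0, loc=4.5, scale=5.0)


def sample_specs(
    n: int,
    angle_distribution=None,
    seed: int = 0,
    laterality: Laterality | str = Laterality.RIGHT,
    noise_sigma: float = 0.0,
    salt_density: float = 0.0,
    landmark_count: int = 59,
) -> list[PhantomSpec]:
    """Draw ``n`` seeded phantom specs with randomized anatomy.

    Angles come from ``angle_distribution`` (a frozen scipy distribution, a
    number for a point mass, or the default skew-normal), truncated by
    rejection to the valid range.  Anatomical parameters (head position and
    radius, knee width and level, plateau curvature) are jittered so that
    shape-model training sets carry genuine shape variation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    laterality = Laterality(laterality)
    rng = np.random.default_rng(seed)
    if angle_distribution is None:
        angle_distribution = default_angle_distribution()

    def draw_angle() -> float:
        if isinstance(angle_distribution, (int, float)):
            return float(angle_distribution)
        for _ in range(1000):
            a = float(angle_distribution.rvs(random_state=rng))
            if 0.0 <= a <= MAX_ANGLE_DEG:
                return a
        raise RuntimeError("angle distribution never hit the valid range")

    specs = []
    for _ in range(n):
        for _attempt in range(100):
            spec = PhantomSpec(
                laterality=laterality,
                head_center=Point(192.0 + rng.uniform(-10, 10), rng.uniform(70, 90)),
                head_radius=rng.uniform(24, 32),
                knee_y=rng.uniform(405, 435),
                knee_width=rng.uniform(80, 100),
                knee_center_x=192.0 + rng.uniform(-8, 8),
                angle_deg=draw_angle(),
                joint_band_height=6.0,
                talus_halfwidth=rng.uniform(25, 31),
                plateau_sag=rng.uniform(5, 9),
                side_depth=rng.uniform(25, 31),
                landmark_count=landmark_count,
                noise_sigma=noise_sigma,
                salt_density=salt_density,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                spec.validate()
                truth = _truth(spec)
                ank = truth.landmarks.ankle_center
                if MARGIN + spec.talus_halfwidth <= ank.x <= spec.width - MARGIN - spec.talus_halfwidth:
                    specs.append(spec)
                    break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not place a valid phantom after 100 attempts")
    return specs


def write_fixture(directory, spec: PhantomSpec, name: str = "phantom") -> dict:
    """Write image (PNG), truth (JSON) and darknet box sidecar for a spec."""
    import imageio.v3 as iio

    from .roi import CLASS_LABELS, write_darknet_boxes

    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img, truth = render(spec)
    iio.imwrite(directory / f"{name}.png", (img * 255).astype(np.uint8))
    with open(directory / f"{name}.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    write_darknet_boxes(
        truth.boxes.values(), directory / f"{name}.txt", spec.width, spec.height,
        {label: i for i, label in enumerate(CLASS_LABELS)},
    )
    return {
        "image": directory / f"{name}.png",
        "truth": directory / f"{name}.json",
        "boxes": directory / f"{name}.txt",
    }
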