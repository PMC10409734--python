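"""Coordinate geometry of the Miniaci opening-wedge osteotomy plan.

All computations live in image pixel coordinates: origin at the top-left
corner, ``x`` increasing rightward, ``y`` increasing *downward*.  Angles are
reported in degrees.

The Miniaci construction, in this frame:

* the **mechanical axis** (MA) joins the femoral head center to the ankle
  joint center;
* the **correction axis** (CA) joins the femoral head center to the
  Fujisawa point — the load-bearing target located 62.5% of the tibial
  plateau width lateral to the medial plateau edge;
* the **hinge point** (HP) is the pivot of the opening wedge, placed from
  the outer (lateral) knee point by fixed fractions of the knee width:
  14% along x toward the inner point and 18% downward;
* the **correction angle** α is measured at HP between the ray to the
  ankle center and the ray to the point G where the extended correction
  axis crosses the ground level.

Rotating the distal limb about HP by α carries the ankle center onto the
correction axis, which is exactly what the osteotomy achieves.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Point",
    "Laterality",
    "LegLandmarks",
    "CorrectionPlan",
    "DegenerateGeometryError",
    "FUJISAWA_FRACTION",
    "HINGE_X_FRACTION",
    "HINGE_Y_FRACTION",
    "fujisawa_point",
    "hinge_point",
    "correction_angle",
    "mechanical_axis_angle",
    "ground_intersection",
    "read_landmarks_json",
    "read_landmarks_csv",
    "write_plan_json",
]

#: Fujisawa point sits at this fraction of the plateau width from the
#: medial edge toward the lateral edge.
FUJISAWA_FRACTION = 0.625
#: Hinge-point offset from the outer knee point, as fractions of knee width.
HINGE_X_FRACTION = 0.14
HINGE_Y_FRACTION = 0.18


class DegenerateGeometryError(ValueError):
    """Raised when an operation receives geometrically degenerate input."""


class Point(NamedTuple):
    """A 2-D point in image pixel coordinates (origin top-left, y down)."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    @staticmethod
    def of(p) -> "Point":
        x, y = float(p[0]), float(p[1])
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"point coordinates must be finite, got {p!r}")
        return Point(x, y)


class Laterality(str, enum.Enum):
    """Which leg a landmark set belongs to.

    Convention for an AP view: for a ``RIGHT`` leg the medial (inner) side
    lies at larger x than the lateral (outer) side; mirrored for ``LEFT``.
    """

    LEFT = "left"
    RIGHT = "right"

    @property
    def medial_sign(self) -> int:
        """Unit x-direction pointing medially (+1 right leg, -1 left leg)."""
        return 1 if self is Laterality.RIGHT else -1


@dataclass(frozen=True)
class LegLandmarks:
    """The named anatomical points of one leg used by the Miniaci plan."""

    femoral_head_center: Point
    medial_plateau_edge: Point
    lateral_plateau_edge: Point
    fujisawa_point: Point
    talus_inner: Point
    talus_outer: Point
    ankle_center: Point
    hinge_point: Point
    laterality: Laterality

    def validate(self, tol: float = 1e-6) -> None:
        """Check internal consistency of the landmark set.

        Verifies that the Fujisawa point lies on the plateau segment, that
        the ankle center is the talus midpoint, and that the medial/lateral
        x-ordering matches the declared laterality.
        """
        m = self.medial_plateau_edge.as_array()
        l = self.lateral_plateau_edge.as_array()
        f = self.fujisawa_point.as_array()
        seg = l - m
        seg_len = np.hypot(*seg)
        if seg_len == 0:
            raise DegenerateGeometryError("plateau edges coincide")
        # distance of F from the infinite line through the plateau edges
        cross = abs(seg[0] * (f[1] - m[1]) - seg[1] * (f[0] - m[0])) / seg_len
        t = float(np.dot(f - m, seg) / (seg_len**2))
        if cross > max(tol, tol * seg_len) or not (-tol <= t <= 1 + tol):
            raise ValueError("fujisawa_point does not lie on the plateau segment")
        mid = 0.5 * (self.talus_inner.as_array() + self.talus_outer.as_array())
        if np.max(np.abs(mid - self.ankle_center.as_array())) > 1e-6 + tol:
            raise ValueError("ankle_center is not the talus midpoint")
        sign = self.laterality.medial_sign
        if (self.medial_plateau_edge.x - self.lateral_plateau_edge.x) * sign <= 0:
            raise ValueError(
                "medial/lateral plateau x-ordering inconsistent with laterality"
            )


@dataclass(frozen=True)
class CorrectionPlan:
    """Result of the Miniaci construction for one leg.

    ``correction_angle_deg`` is signed: positive means a valgus-producing
    (lateral-opening) correction, the usual case for a varus knee.
    """

    mechanical_axis: tuple[Point, Point]
    correction_axis: tuple[Point, Point]
    ground_level_y: float
    correction_angle_deg: float
    hinge_point: Point

    @property
    def deformity(self) -> str:
        if self.correction_angle_deg > 0:
            return "varus"
        if self.correction_angle_deg < 0:
            return "valgus"
        return "neutral"

    def to_dict(self) -> dict:
        (ma0, ma1), (ca0, ca1) = self.mechanical_axis, self.correction_axis
        return {
            "mechanical_axis": [[ma0.x, ma0.y], [ma1.x, ma1.y]],
            "correction_axis": [[ca0.x, ca0.y], [ca1.x, ca1.y]],
            "ground_level_y": self.ground_level_y,
            "correction_angle_deg": self.correction_angle_deg,
            "correction_angle_abs_deg": abs(self.correction_angle_deg),
            "deformity": self.deformity,
            "hinge_point": [self.hinge_point.x, self.hinge_point.y],
        }


def fujisawa_point(medial_edge, lateral_edge) -> Point:
    """Fujisawa point: 62.5% of the way from the medial to the lateral edge."""
    m = Point.of(medial_edge)
    l = Point.of(lateral_edge)
    if m == l:
        raise DegenerateGeometryError("plateau edges coincide")
    return Point(
        m.x + FUJISAWA_FRACTION * (l.x - m.x),
        m.y + FUJISAWA_FRACTION * (l.y - m.y),
    )


def hinge_point(outer_knee, inner_knee, laterality: Laterality | str = Laterality.RIGHT) -> Point:
    """Hinge point from the outer knee point and the knee width.

    The knee width ``W`` is the horizontal distance between the outer and
    inner knee points.  The hinge sits 14% of W along x from the outer point
    toward the inner one, and 18% of W below the outer point.
    """
    o = Point.of(outer_knee)
    i = Point.of(inner_knee)
    width = abs(o.x - i.x)
    if width == 0:
        raise DegenerateGeometryError("zero knee width")
    toward_inner = math.copysign(1.0, i.x - o.x)
    return Point(o.x + HINGE_X_FRACTION * width * toward_inner,
                 o.y + HINGE_Y_FRACTION * width)


def ground_intersection(head: Point, fujisawa: Point, ground_level_y: float) -> Point:
    """Extend the correction axis (head -> Fujisawa) to the ground level."""
    head = Point.of(head)
    fujisawa = Point.of(fujisawa)
    dy = fujisawa.y - head.y
    if dy == 0:
        raise DegenerateGeometryError("correction axis is horizontal; cannot reach ground level")
    t = (ground_level_y - head.y) / dy
    return Point(head.x + t * (fujisawa.x - head.x), float(ground_level_y))


def _signed_angle_at_hinge(hp: Point, ankle: Point, g: Point,
                           laterality: Laterality) -> float:
    """Signed angle (degrees) at HP between the ankle ray and the ground ray.

    Positive sign = valgus-producing correction, i.e. rotating the ankle
    about HP onto the correction axis moves it laterally.  Computed with
    atan2 of cross/dot for stability near zero.
    """
    ua = ankle.as_array() - hp.as_array()
    ug = g.as_array() - hp.as_array()
    if not np.any(ua) or not np.any(ug):
        raise DegenerateGeometryError("ray endpoint coincides with hinge point")
    cross = ua[0] * ug[1] - ua[1] * ug[0]
    dot = float(np.dot(ua, ug))
    theta = math.degrees(math.atan2(cross, dot))
    # theta is the in-plane rotation carrying the ankle ray onto the ground
    # ray; in this frame a math-positive rotation moves a downward-pointing
    # ray toward -x, so the correction is lateral (valgus-producing) exactly
    # when sign(theta) equals the medial x-direction of this leg.
    return laterality.medial_sign * theta


def correction_angle(landmarks: LegLandmarks, ground_level_y: float | None = None) -> CorrectionPlan:
    """Compute the Miniaci correction angle from a full landmark set.

    ``ground_level_y`` defaults to the ankle-center level, which makes the
    angle exactly the rotation about the hinge that carries the ankle onto
    the correction axis.
    """
    head = landmarks.femoral_head_center
    ankle = landmarks.ankle_center
    if ground_level_y is None:
        ground_level_y = ankle.y
    if head.y >= ground_level_y:
        raise DegenerateGeometryError(
            "femoral head center must lie above the ground level"
        )
    if landmarks.fujisawa_point == head:
        raise DegenerateGeometryError("Fujisawa point coincides with femoral head center")
    g = ground_intersection(head, landmarks.fujisawa_point, ground_level_y)
    angle = _signed_angle_at_hinge(landmarks.hinge_point, ankle, g, landmarks.laterality)
    if abs(angle) >= 90:
        raise DegenerateGeometryError(f"implausible correction angle {angle:.1f} deg")
    return CorrectionPlan(
        mechanical_axis=(head, ankle),
        correction_axis=(head, g),
        ground_level_y=float(ground_level_y),
        correction_angle_deg=angle,
        hinge_point=landmarks.hinge_point,
    )


def mechanical_axis_angle(landmarks: LegLandmarks) -> float:
    """Signed angle (degrees) of the mechanical axis against image vertical.

    Positive when the ankle lies at larger x than the femoral head center.
    """
    head = landmarks.femoral_head_center
    ankle = landmarks.ankle_center
    v = ankle.as_array() - head.as_array()
    if not np.any(v):
        raise DegenerateGeometryError("mechanical axis endpoints coincide")
    return math.degrees(math.atan2(v[0], v[1]))


# ---------------------------------------------------------------------------
# landmark / plan I/O

_POINT_FIELDS = (
    "femoral_head_center",
    "medial_plateau_edge",
    "lateral_plateau_edge",
    "fujisawa_point",
    "talus_inner",
    "talus_outer",
    "ankle_center",
    "hinge_point",
)


def _landmarks_from_mapping(rec: dict) -> LegLandmarks:
    kwargs = {}
    for name in _POINT_FIELDS:
        p = rec[name]
        if isinstance(p, dict):
            kwargs[name] = Point.of((p["x"], p["y"]))
        else:
            kwargs[name] = Point.of(p)
    lm = LegLandmarks(laterality=Laterality(rec["laterality"]), **kwargs)
    lm.validate()
    return lm


def read_landmarks_json(path) -> list[LegLandmarks]:
    """Read leg landmark records from a JSON document (list or single)."""
    with open(path) as fh:
        doc = json.load(fh)
    records = doc if isinstance(doc, list) else [doc]
    return [_landmarks_from_mapping(rec) for rec in records]


def read_landmarks_csv(path) -> list[LegLandmarks]:
    """Read leg landmarks from a flat CSV with <field>_x/<field>_y columns."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        rec: dict = {"laterality": row["laterality"]}
        for name in _POINT_FIELDS:
            rec[name] = (row[f"{name}_x"], row[f"{name}_y"])
        out.append(_landmarks_from_mapping(rec))
    return out


def write_plan_json(plans, path) -> None:
    """Write one or more correction plans as a JSON document."""
    if isinstance(plans, CorrectionPlan):
        plans = [plans]
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in plans], fh, indent=2)
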