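"""Tibiotalar joint-space segmentation and talus border points.

The ankle joint center used by the Miniaci construction is derived from
the horizontal radiolucent band between the distal tibia and the talus:
a horizontal Sobel filter highlights the band's edges, the absolute
response is thresholded (Otsu by default), cleaned up by binary opening,
closing and small-object removal, and the dominant near-horizontal
component is kept.  The leftmost and rightmost pixels of that band are the
talus border points; the ankle center is their midpoint.

Detection is sensitive to limb rotation: when the band's principal axis
deviates noticeably from horizontal a :class:`TalusRotationWarning` is
emitted, and bands beyond the hard angle limit are rejected outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure, morphology

from .exceptions import DetectionFailureError, TalusRotationWarning
from .geometry import Laterality, Point
from .utils import as_float_gray

__all__ = ["JointSpaceMask", "segment_joint_space", "talus_border_points", "ankle_center"]


@dataclass
class JointSpaceMask:
    """Binary mask of the dominant joint-space band plus provenance."""

    mask: np.ndarray
    provenance: list[str] = field(default_factory=list)
    band_angle_deg: float = 0.0      # deviation of the principal axis from horizontal


def segment_joint_space(
    roi_image: np.ndarray,
    open_size: int = 3,
    close_size: int = 7,
    min_area_frac: float = 0.001,
    max_band_angle: float = 15.0,
    warn_band_angle: float = 5.0,
    threshold: float | None = None,
) -> JointSpaceMask:
    """Segment the horizontal tibiotalar joint space inside the ankle ROI.

    Pipeline: horizontal Sobel -> |response| -> threshold (Otsu unless an
    explicit value is given) -> opening (horizontal ``1 x open_size``
    element) -> closing (``close_size`` square) -> removal of components
    smaller than ``min_area_frac`` of the ROI -> selection of the largest
    component whose principal axis lies within ``max_band_angle`` degrees
    of horizontal.
    """
    roi = as_float_gray(roi_image)
    prov: list[str] = []
    resp = np.abs(filters.sobel_h(roi))
    prov.append("sobel_h |.|")
    if resp.max() == 0:
        raise DetectionFailureError("zero horizontal-edge response", stage="talus")
    thr = float(filters.threshold_otsu(resp)) if threshold is None else float(threshold)
    binary = resp > thr
    prov.append(f"threshold {'otsu' if threshold is None else 'fixed'}={thr:.4g}")
    # the band's edge response is only a couple of rows thick, so the
    # opening uses a horizontal 1 x open_size element (removes specks
    # without erasing thin horizontal bands); the closing then bridges the
    # band's top and bottom edge responses into one component
    binary = morphology.opening(binary, morphology.footprint_rectangle((1, open_size)))
    binary = morphology.closing(binary, morphology.footprint_rectangle((close_size, close_size)))
    prov.append(f"opening 1x{open_size}, closing {close_size}x{close_size}")
    min_area = max(1, int(min_area_frac * roi.size))
    binary = morphology.remove_small_objects(binary, max_size=min_area - 1)
    prov.append(f"remove_small_objects >= {min_area}")
    if not binary.any():
        raise DetectionFailureError("empty mask after filtering", stage="talus")

    labels = measure.label(binary)
    best = None
    for region in measure.regionprops(labels):
        # regionprops orientation is measured against the row axis; a
        # horizontal band has |orientation| near 90 degrees
        band_angle = 90.0 - abs(np.degrees(region.orientation))
        if band_angle <= max_band_angle:
            if best is None or region.area > best[0].area:
                best = (region, band_angle)
    if best is None:
        raise DetectionFailureError(
            "no near-horizontal band among segmented components",
            stage="talus",
            diagnostics={"n_components": int(labels.max())},
        )
    region, band_angle = best
    if band_angle > warn_band_angle:
        warnings.warn(
            f"joint-space band deviates {band_angle:.1f} deg from horizontal; "
            "the ankle may be rotated and detection unreliable",
            TalusRotationWarning,
            stacklevel=2,
        )
    prov.append(f"dominant band: area={region.area}, angle={band_angle:.2f} deg")
    mask = labels == region.label
    return JointSpaceMask(mask=mask, provenance=prov, band_angle_deg=float(band_angle))


def talus_border_points(
    jsmask: JointSpaceMask,
    roi_origin: tuple[float, float] = (0.0, 0.0),
    laterality: Laterality | str = Laterality.RIGHT,
    min_width: int = 5,
) -> tuple[Point, Point]:
    """Extreme (inner, outer) border points of the segmented band.

    For each extreme column of the band the point sits at the vertical
    midline of the mask in that column; the inner/outer assignment follows
    the leg's laterality (inner = medial side).  Coordinates are mapped to
    full-image coordinates through ``roi_origin``.
    """
    laterality = Laterality(laterality)
    mask = jsmask.mask
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size == 0:
        raise DetectionFailureError("empty joint-space mask", stage="talus")
    if cols[-1] - cols[0] + 1 < min_width:
        raise DetectionFailureError(
            f"band width {cols[-1] - cols[0] + 1} px below minimum {min_width}",
            stage="talus",
        )
    x0, y0 = roi_origin

    def column_point(c: int) -> Point:
        rows = np.flatnonzero(mask[:, c])
        return Point(x0 + float(c), y0 + 0.5 * float(rows[0] + rows[-1]))

    left, right = column_point(int(cols[0])), column_point(int(cols[-1]))
    if laterality.medial_sign > 0:   # medial side at larger x
        return right, left
    return left, right


def ankle_center(inner, outer) -> Point:
    """Ankle joint center as the midpoint of the talus border points."""
    inner, outer = Point.of(inner), Point.of(outer)
    if inner == outer:
        raise ValueError("talus border points coincide")
    return Point(0.5 * (inner.x + outer.x), 0.5 * (inner.y + outer.y))
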