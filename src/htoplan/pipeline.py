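"""End-to-end orchestration: boxes -> landmarks -> correction plan.

Per leg the pipeline runs: femoral head center (Hough) -> knee inner/outer
points (ASM or AAM) -> Fujisawa point -> talus border points and ankle
center (morphological segmentation) -> hinge point -> Miniaci correction
angle.  A failure in any stage marks that leg as failed with the stage
name; the other leg is still processed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import geometry, hough, shapes, talus
from .config import PipelineConfig
from .exceptions import DetectionFailureError
from .geometry import CorrectionPlan, Laterality, LegLandmarks, Point
from .roi import BoundingBox, LegBoxSet, select_leg_boxes
from .shapes import AppearanceModel, LandmarkShape, ProfileModel, ShapeModel
from .utils import as_float_gray, crop, hist_equalize

__all__ = ["KneeModelBundle", "LegResult", "PipelineResult", "process_leg", "run_pipeline"]


@dataclass
class KneeModelBundle:
    """Trained knee models for one laterality."""

    laterality: Laterality
    shape_model: ShapeModel
    profile_model: ProfileModel | None = None
    appearance_model: AppearanceModel | None = None


@dataclass
class LegResult:
    """Outcome for one leg: a plan, or the stage where detection failed."""

    side: str
    laterality: Laterality | None = None
    plan: CorrectionPlan | None = None
    landmarks: LegLandmarks | None = None
    failed_stage: str | None = None
    error: str | None = None
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.plan is not None


@dataclass
class PipelineResult:
    legs: list[LegResult]
    incomplete: dict[str, list[str]] = field(default_factory=dict)

    @property
    def plans(self) -> dict[str, CorrectionPlan]:
        return {r.side: r.plan for r in self.legs if r.ok}


def _init_knee_shape(bundle: KneeModelBundle, box: BoundingBox, scale_frac: float) -> np.ndarray:
    """Mean shape translated to the box center, scaled to the box width."""
    mean = bundle.shape_model.mean_shape
    width = np.ptp(mean[:, 0])
    scale = scale_frac * box.width / width
    pts = mean * scale
    cx, cy = box.center
    return pts - pts.mean(axis=0) + [cx, cy]


def fit_knee(
    image: np.ndarray,
    box: BoundingBox,
    bundle: KneeModelBundle,
    cfg: PipelineConfig,
) -> tuple[Point, Point, LandmarkShape]:
    """Fit the knee model inside its box; returns (inner, outer, shape)."""
    roi, (x0, y0) = crop(image, box.x_min, box.y_min, box.x_max, box.y_max)
    roi = hist_equalize(roi)
    local_box = box.translated(-x0, -y0)
    init = _init_knee_shape(bundle, local_box, cfg.shape.init_scale_frac)
    bounds = (local_box.x_min, local_box.y_min, local_box.x_max, local_box.y_max)
    sc = cfg.shape
    if sc.method == "aam":
        if bundle.appearance_model is None:
            raise DetectionFailureError("no appearance model for this laterality", stage="knee")
        result = shapes.fit_aam(
            roi, bundle.appearance_model, init,
            max_iter=sc.max_iter, rel_tol=sc.aam_rel_tol,
            clamp_sd=sc.clamp_sd, roi_bounds=bounds,
        )
    else:
        if bundle.profile_model is None:
            raise DetectionFailureError("no profile model for this laterality", stage="knee")
        result = shapes.fit_asm(
            roi, bundle.shape_model, bundle.profile_model, init,
            max_iter=sc.max_iter, search_range=sc.search_range,
            clamp_sd=sc.clamp_sd, movement_tol=sc.movement_tol, roi_bounds=bounds,
        )
    fitted = result.shape.translated(x0, y0)
    inner, outer = shapes.knee_points(fitted)
    return inner, outer, fitted


def process_leg(
    image: np.ndarray,
    boxes: LegBoxSet,
    laterality: Laterality,
    bundle: KneeModelBundle,
    cfg: PipelineConfig,
    side: str = "single",
) -> LegResult:
    """Run every stage for one leg, recording per-stage timings."""
    res = LegResult(side=side, laterality=laterality)
    img = as_float_gray(image)
    stage = "femoral_head"
    try:
        t0 = time.perf_counter()
        hc = cfg.hough
        head, _radius = hough.femoral_head_center(
            img, boxes.femoral_head,
            c_lo=hc.radius_c_lo, c_hi=hc.radius_c_hi, radius_step=hc.radius_step,
            sigma=hc.canny_sigma, low_threshold=hc.canny_low, high_threshold=hc.canny_high,
            vote_floor=hc.vote_floor, peak_tolerance=hc.peak_tolerance,
        )
        res.timings[stage] = time.perf_counter() - t0

        stage = "knee"
        t0 = time.perf_counter()
        inner, outer, _shape = fit_knee(img, boxes.knee, bundle, cfg)
        res.timings[stage] = time.perf_counter() - t0

        stage = "talus"
        t0 = time.perf_counter()
        tc = cfg.talus
        roi, origin = crop(img, boxes.ankle.x_min, boxes.ankle.y_min,
                           boxes.ankle.x_max, boxes.ankle.y_max)
        mask = talus.segment_joint_space(
            roi, open_size=tc.open_size, close_size=tc.close_size,
            min_area_frac=tc.min_area_frac, max_band_angle=tc.max_band_angle,
            warn_band_angle=tc.warn_band_angle, threshold=tc.threshold,
        )
        talus_inner, talus_outer = talus.talus_border_points(mask, origin, laterality)
        ankle = talus.ankle_center(talus_inner, talus_outer)
        res.timings[stage] = time.perf_counter() - t0

        stage = "geometry"
        t0 = time.perf_counter()
        fuji = geometry.fujisawa_point(medial_edge=inner, lateral_edge=outer)
        hinge = geometry.hinge_point(outer, inner, laterality)
        landmarks = LegLandmarks(
            femoral_head_center=head,
            medial_plateau_edge=inner,
            lateral_plateau_edge=outer,
            fujisawa_point=fuji,
            talus_inner=talus_inner,
            talus_outer=talus_outer,
            ankle_center=ankle,
            hinge_point=hinge,
            laterality=laterality,
        )
        ground = cfg.geometry.ground_level
        ground_y = ankle.y if ground == "ankle" else float(ground)
        res.plan = geometry.correction_angle(landmarks, ground_y)
        res.landmarks = landmarks
        res.timings[stage] = time.perf_counter() - t0
    except Exception as exc:  # noqa: BLE001 - a failed stage must not abort the other leg
        res.failed_stage = getattr(exc, "stage", None) or stage
        res.error = str(exc)
    return res


def run_pipeline(
    image: np.ndarray,
    boxes: list[BoundingBox],
    models: dict[Laterality, KneeModelBundle],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Plan both legs of an image from detector boxes.

    ``boxes`` is the raw detector output (any number of boxes with
    confidences); legs are assembled with :func:`htoplan.roi.select_leg_boxes`
    and processed left-then-right.  Legs with missing boxes are reported in
    ``incomplete``; stage failures are confined to their leg.
    """
    cfg = config or PipelineConfig()
    img = as_float_gray(image)
    selection = select_leg_boxes(boxes, img.shape[1])
    legs: list[LegResult] = []
    for side in sorted(selection.complete):   # left before right
        triple = selection.complete[side]
        lat_name = cfg.laterality_by_side.get(side, cfg.single_leg_laterality)
        lat = Laterality(lat_name)
        bundle = models.get(lat)
        if bundle is None:
            legs.append(LegResult(side=side, laterality=lat,
                                  failed_stage="knee",
                                  error=f"no knee model for laterality {lat.value}"))
            continue
        legs.append(process_leg(img, triple, lat, bundle, cfg, side=side))
    return PipelineResult(legs=legs, incomplete=dict(selection.incomplete))
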