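"""Helpers to train knee models from phantoms or annotated images."""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .geometry import Laterality
from .phantom import PhantomSpec, render, sample_specs
from .pipeline import KneeModelBundle
from .shapes import LandmarkShape, train_aam, train_asm
from .utils import crop, hist_equalize


def knee_training_data(
    specs: list[PhantomSpec],
) -> tuple[list[np.ndarray], list[LandmarkShape]]:
    """Render phantoms and return equalized knee ROI crops with shapes.

    Shapes are expressed in ROI coordinates, matching how the pipeline
    fits models inside the knee bounding box.
    """
    images, shapes = [], []
    for spec in specs:
        img, truth = render(spec)
        box = truth.boxes["knee"]
        roi, (x0, y0) = crop(img, box.x_min, box.y_min, box.x_max, box.y_max)
        images.append(hist_equalize(roi))
        shapes.append(truth.knee_shape.translated(-x0, -y0))
    return images, shapes


def train_knee_bundle(
    laterality: Laterality | str = Laterality.RIGHT,
    n_train: int = 12,
    landmark_count: int = 59,
    seed: int = 1234,
    config: PipelineConfig | None = None,
    specs: list[PhantomSpec] | None = None,
) -> KneeModelBundle:
    """Train ASM + AAM knee models for one laterality on seeded phantoms."""
    cfg = config or PipelineConfig()
    laterality = Laterality(laterality)
    if specs is None:
        specs = sample_specs(
            n_train, seed=seed, laterality=laterality, landmark_count=landmark_count
        )
    images, shapes = knee_training_data(specs)
    shape_model, profile_model = train_asm(
        images, shapes,
        profile_halfwidth=cfg.shape.profile_halfwidth,
        variance_fraction=cfg.shape.variance_fraction,
    )
    appearance = train_aam(
        images, shapes,
        variance_fraction=cfg.shape.variance_fraction,
        ref_width=cfg.shape.aam_ref_width,
        seed=seed,
    )
    return KneeModelBundle(
        laterality=laterality,
        shape_model=shape_model,
        profile_model=profile_model,
        appearance_model=appearance,
    )
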