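"""Declarative pipeline configuration with schema validation.

All stage tunables live in one validated document; unknown keys are
rejected so that typos in a config file fail loudly instead of silently
using defaults.
"""

from __future__ import annotations

import hashlib
import json

from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HoughConfig(_Strict):
    """Femoral head detection tunables."""

    canny_sigma: float = 1.5
    canny_low: float | None = None
    canny_high: float | None = None
    radius_c_lo: float = 0.5       # of half the shorter bbox side
    radius_c_hi: float = 1.0
    radius_step: int = 1
    vote_floor: float = 0.3        # fraction of the circle perimeter
    peak_tolerance: float = 0.05


class ShapeFitConfig(_Strict):
    """Knee landmark model tunables."""

    method: str = "aam"            # "aam" or "asm"
    landmark_count: int = 59
    variance_fraction: float = 0.98
    profile_halfwidth: int = 6
    search_range: int = 6
    clamp_sd: float = 3.0
    max_iter: int = 40
    movement_tol: float = 0.1      # px, ASM stop criterion
    aam_rel_tol: float = 1e-4
    init_scale_frac: float = 0.8   # model width as a fraction of bbox width
    aam_ref_width: float = 64.0

    @field_validator("method")
    @classmethod
    def _method_known(cls, v: str) -> str:
        if v not in ("asm", "aam"):
            raise ValueError("method must be 'asm' or 'aam'")
        return v

    @field_validator("landmark_count")
    @classmethod
    def _count_known(cls, v: int) -> int:
        if v not in (17, 31, 59):
            raise ValueError("landmark_count must be one of 17, 31, 59")
        return v


class TalusConfig(_Strict):
    """Tibiotalar joint-space segmentation tunables."""

    open_size: int = 3
    close_size: int = 7
    min_area_frac: float = 0.001
    max_band_angle: float = 15.0
    warn_band_angle: float = 5.0
    threshold: float | None = None  # None = Otsu


class GeometryConfig(_Strict):
    """Miniaci construction options."""

    # "ankle" places the ground line at the detected ankle-center level;
    # a number fixes it at that image row.
    ground_level: float | str = "ankle"

    @field_validator("ground_level")
    @classmethod
    def _ground_valid(cls, v):
        if isinstance(v, str) and v != "ankle":
            raise ValueError("ground_level must be 'ankle' or a numeric image row")
        return v


class PipelineConfig(_Strict):
    """Full pipeline configuration, including the seed for reproducibility."""

    hough: HoughConfig = Field(default_factory=HoughConfig)
    shape: ShapeFitConfig = Field(default_factory=ShapeFitConfig)
    talus: TalusConfig = Field(default_factory=TalusConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    seed: int = 0
    # AP-view convention: the image-left leg is the patient's right leg
    laterality_by_side: dict[str, str] = Field(
        default_factory=lambda: {"left": "right", "right": "left"}
    )
    single_leg_laterality: str = "right"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
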