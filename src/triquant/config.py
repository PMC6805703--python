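"""Run configuration: a strict YAML/JSON schema over all pipeline options.

Unknown keys are rejected outright — a typo'd option silently falling back
to a default is the worst failure mode a measurement pipeline can have.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .imaging import DEFAULT_BLUE_COEFFICIENTS, ImagingConfig

__all__ = [
    "ImagingOptions",
    "MetricsOptions",
    "SpectroOptions",
    "PhantomOptions",
    "RunConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ImagingOptions(_Strict):
    orientation: Literal["left_is_left", "flipped"] = "left_is_left"
    background: Literal["white", "black"] = "white"
    threshold_method: Literal["otsu", "fixed"] = "otsu"
    threshold_level: Optional[float] = Field(default=None, gt=0.0, lt=1.0)
    blue_margin: float = Field(default=30 / 255, gt=0.0, lt=1.0)
    filter_coefficients: tuple[float, float, float] = DEFAULT_BLUE_COEFFICIENTS
    use_blue_filter: bool = True
    min_object_px: int = Field(default=64, ge=0)
    background_tolerance: float = Field(default=30 / 255, gt=0.0, lt=1.0)
    min_contrast: float = Field(default=0.15, ge=0.0, le=1.0)
    midline: Optional[int] = None
    blue_scope: Literal["ipsilateral", "slice"] = "ipsilateral"


class MetricsOptions(_Strict):
    normalization: Literal["total_brain", "contralateral"] = "total_brain"
    ipsilateral: Literal["left", "right"] = "right"


class SpectroOptions(_Strict):
    dilution_factor: float = Field(default=4.0, ge=1.0)
    homogenate_volume_ml: float = Field(default=1.0, gt=0.0)
    extrapolation_policy: Literal["clamp", "allow", "error"] = "clamp"


class PhantomOptions(_Strict):
    n_brains: int = Field(default=1, ge=1)
    n_slices: int = Field(default=6, ge=1)
    swelling_factor: float = Field(default=1.0, ge=0.8)
    infarct_fraction: float = Field(default=0.0, ge=0.0, le=0.5)
    eb_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    noise_sd: float = Field(default=6.0, ge=0.0)


class RunConfig(_Strict):
    imaging: ImagingOptions = ImagingOptions()
    metrics: MetricsOptions = MetricsOptions()
    spectro: SpectroOptions = SpectroOptions()
    phantom: PhantomOptions = PhantomOptions()
    seed: int = 0

    def imaging_config(self) -> ImagingConfig:
        """Materialise the frozen per-slice pipeline configuration."""
        opts = self.imaging.model_dump()
        return ImagingConfig(ipsilateral=self.metrics.ipsilateral, **opts)


def load_config(path: Optional[str]) -> RunConfig:
    """Read a YAML (or JSON) config file; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
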