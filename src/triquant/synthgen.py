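"""Seeded phantom generators with recorded ground truth.

Animal-derived scans and plate readings cannot ship with the package, so
recovery testing runs on rendered stand-ins:

* **Brain phantoms** — each coronal slice is two mirrored ellipses meeting
  at the midline.  The right (ipsilateral) ellipse is inflated by a
  swelling factor, an angular wedge of it is painted in the pale infarct
  colour (mimicking the cortical territory of the occluded artery), and an
  inner radial portion of that wedge is painted Evans-blue.  Painted pixel
  counts are recorded before i.i.d. Gaussian channel noise is added, and
  the ground-truth metrics are computed from those counts with the very
  formulas under test.
* **Plate data** — fluorescence is forward-simulated from a known linear
  standard curve, known per-sample extravasation indices and the bench
  dilution arithmetic, optionally with a per-condition multiplicative TTC
  effect on the dye signal for interference experiments.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .imaging import SliceImage, SliceMeasurement

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "PlateData",
    "DEFAULT_RADII",
    "DEFAULT_STANDARD_CONCS_NG_ML",
    "TTC_STANDARD_AMOUNTS_NG",
    "generate_brain",
    "generate_plate_data",
]

#: Per-slice (semi-major, semi-minor) axes in pixels for the default
#: six-slice series: small rostral/caudal slices, large central ones.
DEFAULT_RADII: tuple[tuple[int, int], ...] = (
    (34, 25),
    (40, 29),
    (44, 32),
    (44, 32),
    (40, 29),
    (34, 25),
)

#: Default calibration span, ng/mL: a blank plus the 10-500 ng/mL window
#: used for tissue-sample quantification.
DEFAULT_STANDARD_CONCS_NG_ML: tuple[float, ...] = (0, 10, 25, 50, 100, 200, 350, 500)

#: Dye amounts (ng per 200 uL well) of the wide standard series used in the
#: TTC-interference experiment.
TTC_STANDARD_AMOUNTS_NG: tuple[float, ...] = (0, 50, 100, 250, 500, 1000, 1500, 2000)


@dataclass(frozen=True)
class PhantomParams:
    """Rendering parameters; defaults give a healthy symmetric brain."""

    n_slices: int = 6
    image_shape: tuple[int, int] = (128, 200)  # (H, W)
    hemisphere_radii_px: tuple[tuple[int, int], ...] = DEFAULT_RADII
    swelling_factor: float = 1.0  # right-hemisphere area multiplier
    infarct_fraction: float = 0.0  # of right-hemisphere area, [0, 0.5]
    eb_fraction: float = 0.0  # of infarct area covered by dye, [0, 1]
    viable_color: tuple[int, int, int] = (190, 40, 40)
    infarct_color: tuple[int, int, int] = (235, 230, 225)
    eb_color: tuple[int, int, int] = (45, 45, 170)
    background_color: tuple[int, int, int] = (255, 255, 255)
    noise_sd: float = 6.0  # per-channel Gaussian sigma, 8-bit units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if len(self.hemisphere_radii_px) != self.n_slices:
            raise ValueError("hemisphere_radii_px must list one (a, b) pair per slice")
        if self.swelling_factor < 0.8:
            raise ValueError("swelling_factor must be >= 0.8")
        if not 0.0 <= self.infarct_fraction <= 0.5:
            raise ValueError("infarct_fraction must lie in [0, 0.5]")
        if not 0.0 <= self.eb_fraction <= 1.0:
            raise ValueError("eb_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for col in (
            self.viable_color,
            self.infarct_color,
            self.eb_color,
            self.background_color,
        ):
            if len(col) != 3 or any(not 0 <= v <= 255 for v in col):
                raise ValueError(f"invalid RGB colour {col}")
        h, w = self.image_shape
        m = w // 2
        s = math.sqrt(self.swelling_factor)
        for a, b in self.hemisphere_radii_px:
            if m - 2 * a < 0 or m + 2 * a * s >= w or h / 2 - b * s < 0:
                raise ValueError(
                    "ellipses do not fit the image; enlarge image_shape or shrink radii"
                )


@dataclass(frozen=True)
class PhantomTruth:
    """Painted pixel counts and the metrics they imply (pre-noise)."""

    measurement: _metrics.BrainMeasurement
    infarct_percent: float
    edema_percent: float
    bbb_image_percent: float
    midline_col: int
    eb_total_px: int
    tissue_total_px: int
    params: PhantomParams


def generate_brain(params: PhantomParams = PhantomParams()) -> tuple[list[SliceImage], PhantomTruth]:
    """Render a seeded phantom brain and its ground truth.

    The right ellipse's semi-axes are scaled by ``sqrt(swelling_factor)``
    so its area is ``swelling_factor`` times the left one.  The infarct is
    the elliptical sector of parametric half-angle ``pi * infarct_fraction``
    pointing laterally (sector area is exactly that fraction of the
    ellipse); the Evans-blue zone is the inner radial part of the sector
    with parametric radius ``sqrt(eb_fraction)``, hence exactly
    ``eb_fraction`` of the sector area — strictly inside the infarct.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    m = w // 2
    s = math.sqrt(params.swelling_factor)
    cy = (h - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]

    images: list[SliceImage] = []
    painted: list[SliceMeasurement] = []
    for i, (a, b) in enumerate(params.hemisphere_radii_px, start=1):
        al, bl = float(a), float(b)
        ar, br = al * s, bl * s
        cxl, cxr = m - al, m + ar

        in_left = (((xx - cxl) / al) ** 2 + ((yy - cy) / bl) ** 2 <= 1.0) & (xx < m)
        u = (xx - cxr) / ar
        v = (yy - cy) / br
        in_right = (u**2 + v**2 <= 1.0) & (xx >= m)
        phi = np.arctan2(v, u)
        wedge = in_right & (np.abs(phi) <= math.pi * params.infarct_fraction)
        eb = wedge & (u**2 + v**2 <= params.eb_fraction)

        canvas = np.empty((h, w, 3), dtype=float)
        canvas[:] = params.background_color
        canvas[in_left | in_right] = params.viable_color
        canvas[wedge] = params.infarct_color
        canvas[eb] = params.eb_color

        painted.append(
            SliceMeasurement(
                slice_index=i,
                left_area_px=int(in_left.sum()),
                right_area_px=int(in_right.sum()),
                infarct_area_px=int(wedge.sum()),
                blue_area_px=int(eb.sum()),
            )
        )

        if params.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, params.noise_sd, size=canvas.shape)
        pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
        images.append(SliceImage(pixels, slice_index=i))

    bm = _metrics.aggregate(painted, brain_id=f"phantom-{params.seed}")
    truth = PhantomTruth(
        measurement=bm,
        infarct_percent=_metrics.infarct_percent(bm),
        edema_percent=_metrics.edema_percent(bm),
        bbb_image_percent=_metrics.bbb_image_percent(bm),
        midline_col=m,
        eb_total_px=bm.blue_total_px,
        tissue_total_px=bm.left_total_px + bm.right_total_px,
        params=params,
    )
    return images, truth


# ---------------------------------------------------------------------------
# plate data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateData:
    """Forward-simulated plate: standards, sample reads and the truth table."""

    standards: pd.DataFrame  # ttc_condition, concentration_ng_ml, fluorescence
    samples: pd.DataFrame  # sample_id, ttc_condition, weight_g, ..., fluorescence
    truth: pd.DataFrame  # sample_id, true_ng_per_g
    curve_slope: float
    curve_intercept: float
    seed: int


def generate_plate_data(
    truth_ng_per_g: Sequence[float],
    curve_slope: float = 2.0,
    curve_intercept: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    weights_g: float | Sequence[float] = 0.6,
    homogenate_volume_ml: float = 1.0,
    dilution_factor: float = 4.0,
    standard_concs_ng_ml: Sequence[float] = DEFAULT_STANDARD_CONCS_NG_ML,
    ttc_conditions: Optional[Mapping[str, float]] = None,
) -> PlateData:
    """Forward-simulate a fluorescence plate from known ng/g indices.

    The model inverts the quantification arithmetic: a sample of index
    ``q`` ng/g and weight ``w`` g homogenised in ``V`` mL and diluted by
    ``d`` reads at concentration ``q * w / (d * V)`` ng/mL, hence
    fluorescence ``slope * conc + intercept`` plus Gaussian noise
    (``noise_sd``, fluorescence units).  ``ttc_conditions`` maps condition
    labels to multiplicative effects on the dye signal (1.0 = no
    interference); a "0%" baseline condition is always included.  Standards
    and samples are emitted for every condition with fresh noise, so
    condition readings are paired by sample.
    """
    truth = np.asarray(truth_ng_per_g, dtype=float)
    if truth.size == 0:
        raise ValueError("truth_ng_per_g must be non-empty")
    if np.any(truth < 0):
        raise ValueError("truth indices must be non-negative")
    if curve_slope <= 0:
        raise ValueError("curve_slope must be positive")
    weights = np.broadcast_to(np.asarray(weights_g, dtype=float), truth.shape).copy()
    if np.any(weights <= 0) or homogenate_volume_ml <= 0 or dilution_factor < 1:
        raise ValueError("weights/volume must be positive and dilution >= 1")

    conditions = {"0%": 1.0}
    if ttc_conditions:
        for label, mult in ttc_conditions.items():
            if label != "0%":
                conditions[label] = float(mult)

    rng = np.random.default_rng(seed)
    concs = np.asarray(standard_concs_ng_ml, dtype=float)
    sample_conc = truth * weights / (dilution_factor * homogenate_volume_ml)

    std_rows, sample_rows = [], []
    for label, mult in conditions.items():
        std_f = mult * curve_slope * concs + curve_intercept
        smp_f = mult * curve_slope * sample_conc + curve_intercept
        if noise_sd > 0:
            std_f = std_f + rng.normal(0.0, noise_sd, size=std_f.shape)
            smp_f = smp_f + rng.normal(0.0, noise_sd, size=smp_f.shape)
        for c, f in zip(concs, std_f):
            std_rows.append({"ttc_condition": label, "concentration_ng_ml": c, "fluorescence": f})
        for k, f in enumerate(smp_f):
            sample_rows.append(
                {
                    "sample_id": f"S{k + 1:03d}",
                    "ttc_condition": label,
                    "weight_g": weights[k],
                    "homogenate_volume_ml": homogenate_volume_ml,
                    "dilution_factor": dilution_factor,
                    "fluorescence": f,
                }
            )

    truth_df = pd.DataFrame(
        {"sample_id": [f"S{k + 1:03d}" for k in range(truth.size)], "true_ng_per_g": truth}
    )
    return PlateData(
        standards=pd.DataFrame(std_rows),
        samples=pd.DataFrame(sample_rows),
        truth=truth_df,
        curve_slope=curve_slope,
        curve_intercept=curve_intercept,
        seed=seed,
    )
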