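"""Brain-level injury metrics from per-slice pixel areas.

Three formulas, all on slice-summed hemisphere areas (a volume proxy for
equally thick slices):

* swelling-corrected infarct percentage
      ``corrected = infarct * contra / ipsi``
  expressed against the total brain (``left + right``) or against twice the
  contralateral hemisphere — both normalisations are in circulation and
  both are provided;
* hemispheric edema (Kaplan):
      ``100 * (ipsi - contra) / contra``;
* image-based blood-brain-barrier disruption:
      ``100 * (contra - (ipsi - blue)) / contra``,
  the blue-stained area credited back to the ipsilateral hemisphere before
  comparing it with the contralateral one.  With no blue area this reduces
  to minus the edema value, which is a property of the formula, not a bug.

The occluded (ipsilateral) side is the right hemisphere by default and
configurable on :class:`BrainMeasurement`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .errors import InputError
from .imaging import SliceMeasurement, TissueMask

__all__ = [
    "BrainMeasurement",
    "BrainMetrics",
    "aggregate",
    "infarct_percent",
    "edema_percent",
    "bbb_image_percent",
    "bbb_image_percent_slices",
    "adc_lesion_percent",
    "compute_brain_metrics",
    "EXPECTED_SLICES",
    "ADC_VIABILITY_THRESHOLD",
]

EXPECTED_SLICES = 6

#: ADC below this value (mm^2/s) marks non-viable tissue on diffusion MRI.
ADC_VIABILITY_THRESHOLD = 0.53e-3


@dataclass(frozen=True)
class BrainMeasurement:
    """Ordered slice measurements plus their sums for one brain."""

    brain_id: str
    slices: tuple[SliceMeasurement, ...]
    left_total_px: int
    right_total_px: int
    infarct_total_px: int
    blue_total_px: int
    ipsilateral: str = "right"
    flags: tuple[str, ...] = ()

    @property
    def ipsi_total_px(self) -> int:
        return self.right_total_px if self.ipsilateral == "right" else self.left_total_px

    @property
    def contra_total_px(self) -> int:
        return self.left_total_px if self.ipsilateral == "right" else self.right_total_px


@dataclass(frozen=True)
class BrainMetrics:
    infarct_percent: float
    edema_percent: float
    bbb_image_percent: float
    normalization: str


def aggregate(
    slices: Iterable[SliceMeasurement],
    brain_id: str = "brain",
    ipsilateral: str = "right",
) -> BrainMeasurement:
    """Sum per-slice areas into a brain-level measurement.

    Slice indices must be unique; a slice count other than six is accepted
    but flagged, since the formulas then integrate a partial volume.
    """
    slices = tuple(sorted(slices, key=lambda s: s.slice_index))
    if not slices:
        raise InputError("no slice measurements supplied")
    indices = [s.slice_index for s in slices]
    if len(set(indices)) != len(indices):
        raise InputError(f"duplicate slice_index in {indices}")
    if ipsilateral not in ("left", "right"):
        raise ValueError("ipsilateral must be 'left' or 'right'")
    flags = () if len(slices) == EXPECTED_SLICES else (f"slice-count-{len(slices)}",)
    return BrainMeasurement(
        brain_id=brain_id,
        slices=slices,
        left_total_px=sum(s.left_area_px for s in slices),
        right_total_px=sum(s.right_area_px for s in slices),
        infarct_total_px=sum(s.infarct_area_px for s in slices),
        blue_total_px=sum(s.blue_area_px for s in slices),
        ipsilateral=ipsilateral,
        flags=flags,
    )


def _check_positive(name: str, value: float) -> None:
    if value <= 0:
        raise InputError(f"{name} must be positive, got {value}")


def infarct_percent(bm: BrainMeasurement, normalization: str = "total_brain") -> float:
    """Swelling-corrected infarct volume percentage.

    ``corrected = infarct * contra / ipsi`` removes the edema inflation of
    the occluded hemisphere.  ``"total_brain"`` divides by ``left + right``;
    ``"contralateral"`` divides by ``2 * contra`` (a swelling-free proxy for
    the whole brain).
    """
    _check_positive("ipsilateral hemisphere area", bm.ipsi_total_px)
    _check_positive("contralateral hemisphere area", bm.contra_total_px)
    corrected = bm.infarct_total_px * bm.contra_total_px / bm.ipsi_total_px
    if normalization == "total_brain":
        denom = bm.left_total_px + bm.right_total_px
    elif normalization == "contralateral":
        denom = 2.0 * bm.contra_total_px
    else:
        raise ValueError("normalization must be 'total_brain' or 'contralateral'")
    return 100.0 * corrected / denom


def edema_percent(bm: BrainMeasurement) -> float:
    """Kaplan hemispheric edema: ``100 * (ipsi - contra) / contra``.

    Negative values mean the occluded hemisphere is the smaller one.
    """
    _check_positive("contralateral hemisphere area", bm.contra_total_px)
    return 100.0 * (bm.ipsi_total_px - bm.contra_total_px) / bm.contra_total_px


def bbb_image_percent(bm: BrainMeasurement) -> float:
    """Image-based BBB disruption: ``100 * (contra - (ipsi - blue)) / contra``."""
    _check_positive("contralateral hemisphere area", bm.contra_total_px)
    return (
        100.0
        * (bm.contra_total_px - (bm.ipsi_total_px - bm.blue_total_px))
        / bm.contra_total_px
    )


def bbb_image_percent_slices(bm: BrainMeasurement) -> list[float]:
    """The BBB formula applied slice by slice (for per-slice reporting)."""
    out = []
    for s in bm.slices:
        ipsi = s.right_area_px if bm.ipsilateral == "right" else s.left_area_px
        contra = s.left_area_px if bm.ipsilateral == "right" else s.right_area_px
        _check_positive(f"slice {s.slice_index} contralateral area", contra)
        out.append(100.0 * (contra - (ipsi - s.blue_area_px)) / contra)
    return out


def compute_brain_metrics(bm: BrainMeasurement, normalization: str = "total_brain") -> BrainMetrics:
    """All three metrics in one shot."""
    return BrainMetrics(
        infarct_percent=infarct_percent(bm, normalization),
        edema_percent=edema_percent(bm),
        bbb_image_percent=bbb_image_percent(bm),
        normalization=normalization,
    )


def adc_lesion_percent(
    adc_map: np.ndarray,
    tissue: TissueMask,
    hemispheres: tuple[TissueMask, TissueMask],
    threshold: float = ADC_VIABILITY_THRESHOLD,
    normalization: str = "total_brain",
    ipsilateral: str = "right",
) -> float:
    """Corrected lesion percentage from an apparent-diffusion-coefficient map.

    Tissue pixels with ADC (mm^2/s) below the viability threshold form the
    ischemic lesion; the same swelling-corrected percentage as
    :func:`infarct_percent` is then computed from the hemisphere pixel
    counts.  This lets MRI-derived maps run through the identical ratio
    formulas used for the histological sections.
    """
    adc = np.asarray(adc_map, dtype=float)
    if adc.shape != tissue.shape:
        raise ValueError("ADC map and tissue mask shapes differ")
    if not np.all(np.isfinite(adc[tissue.pixels])) or np.any(adc[tissue.pixels] < 0):
        raise InputError("ADC map contains non-finite or negative values within tissue")
    left, right = hemispheres
    lesion = int((tissue.pixels & (adc < threshold)).sum())
    bm = BrainMeasurement(
        brain_id="adc",
        slices=(),
        left_total_px=left.area_px,
        right_total_px=right.area_px,
        infarct_total_px=lesion,
        blue_total_px=0,
        ipsilateral=ipsilateral,
    )
    return infarct_percent(bm, normalization)
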