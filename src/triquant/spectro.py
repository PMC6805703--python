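"""Fluorometric Evans-blue quantification.

The bench workflow: each hemisphere is weighed, homogenised in 1 mL of 50%
trichloroacetic acid, centrifuged, and the supernatant diluted 1:3 with 96%
ethanol (1 volume supernatant + 3 volumes ethanol -> dilution factor 4).
Fluorescence is read at 620/680 nm excitation/emission and converted to an
Evans-blue concentration through an external standard curve; the
extravasation index is the recovered dye mass per gram of tissue:

    index [ng/g] = conc [ng/mL] * dilution * homogenate volume [mL] / weight [g]

Because the combined protocol pre-incubates slices in TTC before
homogenisation, the module also implements the interference assay: paired
readings of the same samples with and without TTC, expressed as percent of
baseline and compared with the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import CalibrationError, InputError

__all__ = [
    "StandardPoint",
    "StandardCurve",
    "TissueSample",
    "InterferenceResult",
    "WELL_VOLUME_ML",
    "fit_standard_curve",
    "concentration_from_fluorescence",
    "extravasation_index",
    "interference_assay",
]

#: Standard wells hold 200 uL, so amount [ng] / 0.2 = concentration [ng/mL].
WELL_VOLUME_ML = 0.2


@dataclass(frozen=True)
class StandardPoint:
    """One calibration well: known Evans-blue content and its fluorescence.

    Provide either ``amount_ng`` (dye mass in a 200 uL well) or
    ``concentration_ng_ml`` directly.
    """

    fluorescence: float
    amount_ng: Optional[float] = None
    concentration_ng_ml: Optional[float] = None
    ttc_condition: str = "0%"

    def __post_init__(self) -> None:
        if (self.amount_ng is None) == (self.concentration_ng_ml is None):
            raise ValueError("provide exactly one of amount_ng / concentration_ng_ml")
        if self.amount_ng is not None:
            if self.amount_ng < 0:
                raise ValueError("amount_ng must be >= 0")
            object.__setattr__(self, "concentration_ng_ml", self.amount_ng / WELL_VOLUME_ML)
        elif self.concentration_ng_ml < 0:
            raise ValueError("concentration_ng_ml must be >= 0")
        if not math.isfinite(self.fluorescence):
            raise ValueError("fluorescence must be finite")


@dataclass(frozen=True)
class StandardCurve:
    """Linear fluorescence-vs-concentration calibration."""

    slope: float  # fluorescence a.u. per (ng/mL)
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]  # ng/mL, observed concentration span
    n_points: int = 0
    ttc_condition: str = "0%"


@dataclass(frozen=True)
class TissueSample:
    """One homogenised hemisphere sample and its diluted-read fluorescence."""

    sample_id: str
    fluorescence: float
    tissue_weight_g: float
    hemisphere: str = "right"
    homogenate_volume_ml: float = 1.0
    dilution_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.tissue_weight_g <= 0:
            raise InputError(f"{self.sample_id}: tissue weight must be positive")
        if self.homogenate_volume_ml <= 0:
            raise ValueError("homogenate volume must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass(frozen=True)
class InterferenceResult:
    """One row of the TTC-interference table."""

    condition: str
    percent_of_baseline: float
    sem: float
    variability: float  # max - min of the percent values
    p_value: Optional[float]
    significant: Optional[bool]
    n_pairs: int
    r_squared: Optional[float] = None
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------


def fit_standard_curve(points: Sequence[StandardPoint]) -> StandardCurve:
    """Ordinary least-squares line of fluorescence on concentration (ng/mL).

    The blank (0 ng) is an ordinary point; the intercept is not forced
    through zero.  At least two points with two distinct concentrations are
    required.
    """
    if len(points) < 2:
        raise CalibrationError("need at least two standard points")
    conc = np.array([p.concentration_ng_ml for p in points], dtype=float)
    fluo = np.array([p.fluorescence for p in points], dtype=float)
    if np.unique(conc).size < 2:
        raise CalibrationError("standards must span at least two distinct concentrations")
    fit = sps.linregress(conc, fluo)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        valid_range=(float(conc.min()), float(conc.max())),
        n_points=len(points),
        ttc_condition=points[0].ttc_condition,
    )


def concentration_from_fluorescence(
    fluorescence: float,
    curve: StandardCurve,
    extrapolation_policy: str = "clamp",
) -> float:
    """Inverse prediction: ``(f - intercept) / slope`` in ng/mL.

    ``"clamp"`` truncates into [0, top of valid range], ``"allow"`` returns
    the raw value (including negatives), ``"error"`` raises outside the
    calibrated span.
    """
    if curve.slope <= 0:
        raise CalibrationError("standard curve slope must be positive for inversion")
    conc = (fluorescence - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    if extrapolation_policy == "allow":
        return conc
    if extrapolation_policy == "clamp":
        return float(min(max(conc, 0.0), hi))
    if extrapolation_policy == "error":
        if conc < lo or conc > hi:
            raise CalibrationError(
                f"predicted {conc:.3g} ng/mL outside calibrated range [{lo:.3g}, {hi:.3g}]"
            )
        return conc
    raise ValueError("extrapolation_policy must be 'clamp', 'allow' or 'error'")


def extravasation_index(
    sample: TissueSample,
    curve: StandardCurve,
    extrapolation_policy: str = "clamp",
) -> float:
    """Evans blue recovered per gram of tissue (ng/g)."""
    conc = concentration_from_fluorescence(sample.fluorescence, curve, extrapolation_policy)
    total_ng = conc * sample.dilution_factor * sample.homogenate_volume_ml
    return total_ng / sample.tissue_weight_g


# ---------------------------------------------------------------------------
# TTC interference assay
# ---------------------------------------------------------------------------


def _percent_row(
    condition: str,
    percents: np.ndarray,
    p_value: Optional[float],
    alpha: float,
    r_squared: Optional[float],
    flags: tuple[str, ...],
) -> InterferenceResult:
    sem = float(sps.sem(percents)) if percents.size > 1 else 0.0
    return InterferenceResult(
        condition=condition,
        percent_of_baseline=float(percents.mean()),
        sem=sem,
        variability=float(percents.max() - percents.min()),
        p_value=p_value,
        significant=None if p_value is None else bool(p_value < alpha),
        n_pairs=int(percents.size),
        r_squared=r_squared,
        flags=flags,
    )


def interference_assay(
    baseline: Sequence[float],
    conditions: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    standards: Optional[Mapping[str, Sequence[StandardPoint]]] = None,
) -> list[InterferenceResult]:
    """Compare paired readings at each TTC condition against the 0% baseline.

    ``baseline`` and every condition must hold the same samples in the same
    order.  Each pair is expressed as ``100 * condition / baseline`` for the
    table; the hypothesis test is a two-sided Wilcoxon signed-rank on the
    raw paired readings (exact null distribution when sample size permits
    and there are no ties).  The baseline row normalises each replicate
    against the baseline mean, so it reads 100% with a non-zero SEM.

    ``standards`` may map condition labels to calibration points, in which
    case each row also carries the R-squared of that condition's standard
    curve.
    """
    base = np.asarray(baseline, dtype=float)
    if base.size < 2:
        raise InputError("baseline needs at least two readings")
    if np.all(base == 0):
        raise InputError("baseline readings are all zero")
    results = []

    def _rsq(label: str) -> Optional[float]:
        if standards is None or label not in standards:
            return None
        return fit_standard_curve(list(standards[label])).r_squared

    results.append(
        _percent_row("0%", 100.0 * base / base.mean(), None, alpha, _rsq("0%"), ())
    )
    for label, readings in conditions.items():
        cond = np.asarray(readings, dtype=float)
        if cond.size != base.size:
            raise InputError(
                f"condition {label!r} has {cond.size} readings, baseline has {base.size}"
            )
        flags: tuple[str, ...] = ("underpowered",) if cond.size < 5 else ()
        diffs = cond - base
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(cond, base, alternative="two-sided", method="auto").pvalue)
        with np.errstate(divide="raise", invalid="raise"):
            try:
                percents = 100.0 * cond / base
            except FloatingPointError as exc:
                raise InputError(f"condition {label!r}: zero baseline reading in a pair") from exc
        results.append(_percent_row(label, percents, p, alpha, _rsq(label), flags))
    return results
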