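"""End-to-end recovery studies on synthetic ground truth.

Each function here sets up a seeded phantom or plate experiment, runs the
measurement pipeline exactly as a user would, and reduces the outcome to a
handful of summary numbers (recovery slope, maximum error, rejection
rate...).  They double as the package's self-validation: the test suite
asserts on their outputs and ``scripts/acceptance.py`` reports them.

Problem sizes are kept at desk scale (tens of phantoms of ~128x200 px,
hundreds of simulated assays) — large enough for stable summary statistics,
small enough to run in seconds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import metrics, spectro, synthgen
from .imaging import ImagingConfig, measure_slice

__all__ = [
    "formula_consistency",
    "filter_ablation_study",
    "infarct_edema_recovery",
    "bbb_concordance",
    "plate_round_trip",
    "interference_calibration",
]

_BASE_CONFIG = ImagingConfig()


def measure_phantom(
    images,
    config: ImagingConfig = _BASE_CONFIG,
    brain_id: str = "phantom",
) -> metrics.BrainMeasurement:
    """Measure every slice of a rendered phantom and aggregate."""
    return metrics.aggregate(
        [measure_slice(img, config) for img in images],
        brain_id=brain_id,
        ipsilateral=config.ipsilateral,
    )


# ---------------------------------------------------------------------------


def formula_consistency(n_tables: int = 20, seed: int = 0) -> dict:
    """Check the three formulas against independent direct arithmetic.

    Random integer area tables are pushed through the metrics module and
    through formulas re-derived inline here; returns the maximum absolute
    discrepancy over all tables and all five outputs (expected: 0.0 up to
    float round-off).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        left = int(rng.integers(500, 5000))
        right = int(rng.integers(500, 5000))
        infarct = int(rng.integers(0, min(left + right, right)))
        blue = int(rng.integers(0, right))
        sm = [
            metrics.SliceMeasurement(i + 1, left // 6 + (i == 0) * (left % 6),
                                     right // 6 + (i == 0) * (right % 6),
                                     infarct // 6 + (i == 0) * (infarct % 6),
                                     blue // 6 + (i == 0) * (blue % 6))
            for i in range(6)
        ]
        bm = metrics.aggregate(sm)
        # independent route: the formulas written out longhand
        corrected = infarct * left / right
        expected = {
            "infarct_total": 100 * corrected / (left + right),
            "infarct_contra": 100 * corrected / (2 * left),
            "edema": 100 * (right - left) / left,
            "bbb": 100 * (left - (right - blue)) / left,
        }
        got = {
            "infarct_total": metrics.infarct_percent(bm, "total_brain"),
            "infarct_contra": metrics.infarct_percent(bm, "contralateral"),
            "edema": metrics.edema_percent(bm),
            "bbb": metrics.bbb_image_percent(bm),
        }
        for key in expected:
            worst = max(worst, abs(expected[key] - got[key]))
    return {"max_abs_error": worst, "n_tables": n_tables}


def filter_ablation_study(
    n_phantoms: int = 20,
    seed: int = 0,
    eb_range: tuple[float, float] = (0.5, 1.0),
    infarct_range: tuple[float, float] = (0.06, 0.14),
    swelling_range: tuple[float, float] = (1.0, 1.15),
) -> dict:
    """Measure dyed phantoms with and without the blue filter.

    Each phantom's Evans-blue zone covers ``eb_range`` of its infarct.
    Reports the largest deviation of the blue-filtered infarct percentage
    from the dye-free painted truth (percentage points) and the mean
    relative shortfall of the unfiltered-luminance measurement (the dyed
    pixels it "loses" to the viable class).
    """
    rng = np.random.default_rng(seed)
    filtered_err, underestimate = [], []
    for k in range(n_phantoms):
        params = synthgen.PhantomParams(
            infarct_fraction=float(rng.uniform(*infarct_range)),
            swelling_factor=float(rng.uniform(*swelling_range)),
            eb_fraction=float(rng.uniform(*eb_range)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        images, truth = synthgen.generate_brain(params)
        filt = metrics.infarct_percent(measure_phantom(images))
        unfilt = metrics.infarct_percent(
            measure_phantom(images, replace(_BASE_CONFIG, use_blue_filter=False))
        )
        filtered_err.append(filt - truth.infarct_percent)
        underestimate.append(1.0 - unfilt / truth.infarct_percent)
    return {
        "n_phantoms": n_phantoms,
        "filtered_max_abs_err_pp": float(np.max(np.abs(filtered_err))),
        "unfiltered_min_underestimate": float(np.min(underestimate)),
        "unfiltered_mean_underestimate": float(np.mean(underestimate)),
    }


def infarct_edema_recovery(
    n_phantoms: int = 30,
    seed: int = 0,
    infarct_range: tuple[float, float] = (0.0, 0.14),
    swelling_range: tuple[float, float] = (1.0, 1.15),
) -> dict:
    """Sweep infarct fraction and swelling; regress measured on truth.

    Returns the slope and Pearson r of measured-vs-true infarct percentage
    and the largest absolute edema error in percentage points.
    """
    rng = np.random.default_rng(seed)
    fracs = np.linspace(*infarct_range, n_phantoms)
    rows = []
    for k, frac in enumerate(fracs):
        params = synthgen.PhantomParams(
            infarct_fraction=float(frac),
            swelling_factor=float(rng.uniform(*swelling_range)),
            eb_fraction=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        images, truth = synthgen.generate_brain(params)
        bm = measure_phantom(images)
        rows.append(
            {
                "true_infarct_pct": truth.infarct_percent,
                "measured_infarct_pct": metrics.infarct_percent(bm),
                "true_edema_pct": truth.edema_percent,
                "measured_edema_pct": metrics.edema_percent(bm),
            }
        )
    df = pd.DataFrame(rows)
    fit = sps.linregress(df["true_infarct_pct"], df["measured_infarct_pct"])
    return {
        "n_phantoms": n_phantoms,
        "slope": float(fit.slope),
        "r": float(fit.rvalue),
        "edema_max_abs_err_pp": float(
            (df["measured_edema_pct"] - df["true_edema_pct"]).abs().max()
        ),
        "table": df,
    }


def bbb_concordance(
    n_phantoms: int = 12,
    seed: int = 0,
    infarct_fraction: float = 0.12,
    swelling_factor: float = 1.08,
) -> dict:
    """Image-based BBB percentage vs ground-truth dye coverage.

    Sweeps the Evans-blue fraction at fixed injury geometry; the image
    metric should track the painted dye fraction linearly, mirroring the
    imaging-vs-spectroscopy concordance seen on real brains.
    """
    rng = np.random.default_rng(seed)
    eb_fracs = np.linspace(0.05, 0.95, n_phantoms)
    measured, true_frac = [], []
    for frac in eb_fracs:
        params = synthgen.PhantomParams(
            infarct_fraction=infarct_fraction,
            swelling_factor=swelling_factor,
            eb_fraction=float(frac),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        images, truth = synthgen.generate_brain(params)
        bm = measure_phantom(images)
        measured.append(metrics.bbb_image_percent(bm))
        true_frac.append(truth.eb_total_px / truth.tissue_total_px)
    r = sps.pearsonr(true_frac, measured)
    return {"n_phantoms": n_phantoms, "r": float(r.statistic)}


# ---------------------------------------------------------------------------


def _fit_and_index(
    plate: synthgen.PlateData,
    condition: str = "0%",
    curve_condition: str | None = None,
) -> np.ndarray:
    """Quantify one condition's samples against a standard curve.

    By default the curve is fitted on the same condition's standards;
    interference studies instead quantify every condition against the
    baseline ("0%") curve, as a lab reusing its dye calibration would.
    """
    curve_condition = condition if curve_condition is None else curve_condition
    std = plate.standards[plate.standards["ttc_condition"] == curve_condition]
    curve = spectro.fit_standard_curve(
        [
            spectro.StandardPoint(
                fluorescence=row.fluorescence,
                concentration_ng_ml=row.concentration_ng_ml,
                ttc_condition=curve_condition,
            )
            for row in std.itertuples()
        ]
    )
    smp = plate.samples[plate.samples["ttc_condition"] == condition]
    return np.array(
        [
            spectro.extravasation_index(
                spectro.TissueSample(
                    sample_id=row.sample_id,
                    fluorescence=row.fluorescence,
                    tissue_weight_g=row.weight_g,
                    homogenate_volume_ml=row.homogenate_volume_ml,
                    dilution_factor=row.dilution_factor,
                ),
                curve,
            )
            for row in smp.itertuples()
        ]
    )


def plate_round_trip(
    n_samples: int = 20,
    noise_frac: float = 0.01,
    seed: int = 0,
    index_range: tuple[float, float] = (500.0, 3000.0),
) -> dict:
    """Generate plates at known ng/g, recalibrate, invert, compare.

    Noise sigma is ``noise_frac`` of the top-of-curve signal.  Reports the
    noiseless maximum relative error (machine precision) and, for the noisy
    plate, the relative mean absolute error
    ``mean(|est - truth|) / mean(truth) * 100``.
    """
    rng = np.random.default_rng(seed)
    truth = rng.uniform(*index_range, size=n_samples)
    clean = synthgen.generate_plate_data(truth, noise_sd=0.0, seed=seed)
    est0 = _fit_and_index(clean)
    noiseless_err = float(np.max(np.abs(est0 - truth) / truth))

    max_signal = (
        clean.curve_slope * max(synthgen.DEFAULT_STANDARD_CONCS_NG_ML) + clean.curve_intercept
    )
    noisy = synthgen.generate_plate_data(
        truth, noise_sd=noise_frac * max_signal, seed=seed + 1
    )
    est = _fit_and_index(noisy)
    mae_pct = float(np.mean(np.abs(est - truth)) / np.mean(truth) * 100.0)
    return {
        "n_samples": n_samples,
        "noiseless_max_rel_err": noiseless_err,
        "relative_mae_pct": mae_pct,
    }


def interference_calibration(
    n_assays: int = 500,
    n_pairs: int = 10,
    effect: float = 1.0,
    noise_frac: float = 0.01,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Monte-Carlo the interference assay's Wilcoxon decision.

    ``effect`` is the multiplicative TTC effect on the dye signal; 1.0
    simulates the no-interference null (rejection rate should sit at the
    exact test's size, ~0.049 for ten pairs), 1.5 a gross interference
    (rejection rate = power).  Each assay quantifies the same ``n_pairs``
    samples with and without TTC through their own standard curves, exactly
    as the bench comparison does.
    """
    rng = np.random.default_rng(seed)
    max_signal = 2.0 * max(synthgen.DEFAULT_STANDARD_CONCS_NG_ML) + 50.0
    rejections = 0
    for k in range(n_assays):
        truth = rng.uniform(800.0, 3000.0, size=n_pairs)
        plate = synthgen.generate_plate_data(
            truth,
            noise_sd=noise_frac * max_signal,
            seed=int(rng.integers(0, 2**31 - 1)),
            ttc_conditions={"ttc": effect},
        )
        base = _fit_and_index(plate, "0%")
        cond = _fit_and_index(plate, "ttc", curve_condition="0%")
        result = spectro.interference_assay(base, {"ttc": cond}, alpha=alpha)[1]
        rejections += bool(result.significant)
    return {"n_assays": n_assays, "rejection_rate": rejections / n_assays}
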