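# Methods

`triquant` quantifies three read-outs of ischemic brain injury from a
*single* set of TTC / Evans-blue double-stained coronal slices: infarct
volume, hemispheric edema, and blood-brain-barrier (BBB) disruption —
the last both from scanned images and from fluorometric plate readings.
This note records the model, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## The measurement model

A scanned slice carries three colour populations: TTC-red viable tissue,
pale (near-white) unstained infarct, and dark-blue Evans-blue
extravasation. Quantities are pixel counts; with equally thick slices,
slice-summed areas are proportional to volumes, so all brain-level
formulas operate on the six-slice sums.

**Blue channel-mixer filter.** Converting the scan to ordinary luminance
makes Evans-blue pixels *dark* — they are classified as viable tissue and
the infarct disappears from the count. The filter replaces luminance with a
linear channel mix, by default monochrome = 100% blue channel
(coefficients `(0, 0, 1)`, each allowed in [-2, 2]). Under that mix the
dye (B ≈ 170) and pale infarct (B ≈ 225) are both bright while TTC-red
tissue (B ≈ 40) is dark, so one threshold recovers the full infarct
regardless of dye coverage. The exact channel-mixer percentages used on
real scanners are a free parameter; `(0, 0, 1)` is the choice that
reproduces the qualitative effect and is exposed in the config.

**Segmentation.** Foreground is every pixel whose *Euclidean* RGB distance
from the declared background colour (white by default) exceeds a tolerance
(default 30/255). Euclidean distance rather than a per-channel maximum is
deliberate: pale infarct sits close to a white background on every single
channel but is comfortably separated in joint RGB distance, so the
per-channel rule is brittle exactly where it matters most. Components
smaller than `min_object_px` (default 64) are treated as debris and
interior holes are filled.

**Hemisphere split.** The midline defaults to the interhemispheric
"waist": the column with the least tissue inside the central mass window
(between the 25% and 75% column-mass quantiles), accepted only when it is
a clear notch (below half the window median), otherwise the centroid
column. A centroid midline is exact for symmetric slices but migrates into
a swollen hemisphere — precisely the condition the edema metric exists to
measure — which is why the notch detector is the default. An explicit
midline column (operator-drawn, or recorded by the phantom generator)
always takes precedence.

**Infarct threshold.** Otsu's criterion on the within-tissue histogram,
computed over the *exact* empirical gray levels (not histogram bins), with
ties broken toward the smaller threshold; pixels at or above the threshold
are infarct. Two degenerate cases are declared infarct-free and flagged
rather than guessed at: a single-valued histogram, and a split whose class
means differ by less than `min_contrast` (default 0.15 in [0, 1] gray
units). The guard matters because Otsu applied to a unimodal noise
histogram happily bisects the noise; the stain populations in both real
scans and the phantoms are separated by ~0.5–0.7 gray units, so 0.15 is
far below any genuine infarct contrast and far above sensor noise
(σ ≈ 0.02). A fixed-level threshold is available as an override.

**Blue detection** runs on the raw RGB scan (never the filtered image):
a tissue pixel is Evans-blue iff `(B - max(R, G)) / 255 > blue_margin`
(default 30/255). The rule is hue-free and monotone in the margin. Blue
pixels are attributed to the ipsilateral (right, occluded) hemisphere by
default, with a whole-slice option, since the BBB formula subtracts the
stained area from the ipsilateral term.

## Brain-level formulas

With slice-summed left/contralateral area L, right/ipsilateral area R,
infarct area I and blue-stained area B (all pixels):

* corrected infarct: `I' = I * L / R`, reported as `100 * I' / (L + R)`
  ("total_brain", default) or `100 * I' / (2L)` ("contralateral") — both
  normalisations circulate in the literature and the switch is explicit;
* edema (Kaplan): `100 * (R - L) / L`, negative if the occluded side is
  smaller;
* image-based BBB disruption: `100 * (L - (R - B)) / L`. With B = 0 this
  is exactly minus the edema value — the formula couples dye area and
  swelling by construction, and the package reports it as defined.

The same corrected-percentage arithmetic applies to MRI-derived inputs:
`adc_lesion_percent` thresholds an apparent-diffusion-coefficient map at
0.53 × 10⁻³ mm²/s (pixels below are lesion) and feeds the counts through
the identical ratio formulas.

## Fluorometric quantification

Standard curves are unweighted ordinary least squares of fluorescence on
concentration (ng/mL); the blank is an ordinary point and the intercept is
free. Standard wells hold 200 µL, so an amount of *a* ng corresponds to
*a*/0.2 ng/mL. The default validity window for tissue quantification is
the 10–500 ng/mL external-standard range; inverse prediction policy is
configurable (`clamp` to [0, top of range], `allow`, or `error`).

The extravasation index is
`conc * dilution * homogenate_volume / weight` (ng per g tissue). The
"diluted 1:3 with ethanol" bench step is read as 1 volume supernatant + 3
volumes ethanol, i.e. dilution factor 4; labs that read 1:3 as a final
factor of 3 can set it so — the factor linearly scales every index, which
is why it is an explicit parameter rather than a constant.

The TTC-interference assay takes paired readings of the same samples with
and without TTC. Each pair is expressed as `100 * condition / baseline`
for the table (mean ± SEM plus a max-minus-min variability column); the
baseline row normalises each replicate against the baseline mean so it
reads 100% with a non-zero SEM. The hypothesis test is a two-sided
Wilcoxon signed-rank on the raw paired readings, using the exact null
distribution whenever sample size and absence of ties permit; fewer than
five pairs is flagged as underpowered.

## Statistical gating

Group comparisons route through an explicit gate: Welch's t-test (Cohen's
d) only when both groups pass a Lilliefors-corrected Kolmogorov–Smirnov
normality check at α = 0.05 *and* have n ≥ 8; otherwise the two-sided
Mann–Whitney U with the rank-biserial correlation. The Lilliefors variant
(normal with estimated parameters) is what a "K-S normality check" means
in practice; a K-S test against a fully specified normal is almost never
intended. Welch rather than pooled-variance t is the default because
equal variances cannot be assumed between lesioned and sham groups.
Correlations use Pearson only for normal variables with n > 30, otherwise
Spearman. Interval scale is asserted by the caller; it cannot be inferred
from numbers. The routing rationale is part of every result object.

## The phantom generator

Each slice is two mirrored ellipses touching at the midline; the default
series of six uses semi-axes (34,25), (40,29), (44,32), (44,32), (40,29),
(34,25) px on a 128 × 200 canvas. The right ellipse's axes are scaled by
√(swelling factor), so its area is exactly the swelling factor times the
left one. The infarct is the elliptical sector of parametric half-angle
π · infarct_fraction pointing laterally (sector area is exactly that
fraction of the ellipse); the Evans-blue zone is the inner radial part of
the sector with parametric radius √(eb_fraction), hence exactly
eb_fraction of the sector area and strictly inside the infarct. Default
colours follow the qualitative appearance of stained slices — viable
(190, 40, 40), infarct (235, 230, 225), dye (45, 45, 170) on white — and
are configurable since no colorimetry is published. Noise is i.i.d.
Gaussian per channel (σ = 6 of 255) added after the truth counts are
recorded; identical seeds give bit-identical images.

What the phantoms do **not** emulate: scanner vignetting and JPEG
artifacts, slice deformation and slice-to-slice shape continuity,
anatomically realistic lesion geometry, dye extending *beyond* the
infarct. The last point is a known property of the method itself, not of
the phantoms: the blue filter maps any Evans-blue pixel bright, so dye
outside the pale infarct would be counted as infarct. Passing recovery
tests therefore demonstrate the pipeline's arithmetic and its robustness
to sensor noise and rasterisation — not robustness to real-tissue
morphology.

Plate data are forward-simulated from the inverse of the quantification
arithmetic (sample concentration = index · weight / (dilution · volume)),
with Gaussian read noise in fluorescence units and an optional
multiplicative TTC effect on the dye signal per condition; standards and
samples are emitted per condition with fresh noise, paired by sample.

## Validation studies and problem sizes

The `validation` module re-runs the pipeline end to end; the test suite
asserts on its outputs and `scripts/acceptance.py` reports them. Sizes
were chosen to make the summary statistics stable at desk scale: 20
phantom brains for the filter-ablation study (dye covering 50–100% of the
infarct), 30 for the infarct/edema recovery sweep (infarct fraction 0–14%
of the right hemisphere, swelling 1.00–1.15), 12 for the dye-coverage
sweep, 20 samples per plate, and 500 simulated assays of 10 pairs for the
Wilcoxon size check (the exact test's true size at ten pairs is 0.0488).
Plate round-trip samples draw true indices from 500–3000 ng/g with 0.6 g
hemisphere weights, placing diluted concentrations of 75–450 ng/mL inside
the 10–500 ng/mL calibration window, as a lab would dilute to; recovery
error is reported as relative MAE, `mean(|est - truth|) / mean(truth)`,
since a per-sample relative error is unbounded for near-zero indices.

## Known limitations

* The hemisphere split assumes a roughly vertical midline; heavily rotated
  scans need an explicit midline or pre-rotation.
* The image-based BBB formula inherits its edema coupling; do not
  interpret it in isolation from the edema value.
* Dye outside the infarct is counted as infarct by the filtered threshold
  (documented above, not corrected).
* The 16-bit → 8-bit loader uses integer division (floor), matching
  scanner-export behaviour, so it is not round-trip exact with rounding
  conversions.
* Condition labels in the interference assay are free-form strings; the
  package does not police which TTC concentrations were actually used.
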