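# triquant

Quantify three read-outs of ischemic stroke injury — **infarct volume**,
**hemispheric edema** and **blood-brain-barrier (BBB) disruption** — from a
*single* set of TTC / Evans-blue double-stained rodent brain slices, plus
fluorometric Evans-blue quantification with standard-curve calibration.

Classically each read-out consumes its own cohort of animals: TTC staining
for infarct, hemisphere volumetry for edema, Evans-blue spectrometry for
BBB leakage. Measuring all three on one brain fails naively because
Evans-blue-stained infarct turns *dark* under ordinary grayscale
conversion and is miscounted as viable tissue. `triquant` implements the
combined protocol around a blue channel-mixer filter (monochrome = 100%
blue channel) that maps the dye and the pale infarct bright and the
TTC-red tissue dark, making infarct thresholding immune to the dye — so a
single slice series yields every metric. The package is aimed at
experimental-stroke labs replacing a manual Photoshop/ImageJ workflow
with a scripted, testable one.

## The quantities

With slice-summed pixel areas — L (left/contralateral hemisphere),
R (right/ipsilateral), I (infarct), B (blue-stained):

* corrected infarct: I′ = I · L/R, reported as 100 · I′/(L+R) (or
  100 · I′/2L with the `contralateral` normalisation),
* edema (Kaplan): 100 · (R − L)/L,
* image-based BBB disruption: 100 · (L − (R − B))/L,
* extravasation index: c · d · V / w ng of Evans blue per gram of tissue,
  with concentration c from inverse prediction on a linear standard
  curve, dilution factor d, homogenate volume V, tissue weight w,
* the TTC-interference table: percent-of-baseline ± SEM per TTC
  concentration with two-sided exact Wilcoxon signed-rank p-values.

## Worked example

Simulate a phantom brain with known injury, then measure it:

```sh
triquant simulate --seed 3 --out demo --config injury.yaml
triquant analyze demo/phantom001 --out demo-metrics --ablate-filter
```

with `injury.yaml`:

```yaml
phantom:
  infarct_fraction: 0.10   # 10% of the right hemisphere
  swelling_factor: 1.08    # right hemisphere inflated 8%
  eb_fraction: 0.5         # dye covers half the infarct
```

`demo-metrics/phantom001_metrics.json` then reads (this exact output, seed 3):

```json
{
  "brain_id": "phantom001",
  "normalization": "total_brain",
  "infarct_percent": 4.8107,
  "edema_percent": 8.1856,
  "bbb_image_percent": -2.8125,
  "infarct_percent_unfiltered": 2.425
}
```

Reading the numbers: the painted truth for this phantom (recorded in
`demo/phantom001/phantom001_truth.json`) is 4.8124% infarct and 8.1903%
edema — both recovered to two decimals. The blue-filtered infarct
(4.81%) is unaffected by the dye, while the `--ablate-filter` rerun
without the filter (2.43%) loses half the infarct to the dye — the
failure mode the filter exists to fix. The negative image-BBB value
reflects that formula's built-in edema coupling (with no blue area it
equals minus the edema); it grows with dye area.

The same pipeline is available as a library:

```python
from triquant import PhantomParams, generate_brain, measure_slice, aggregate, compute_brain_metrics

images, truth = generate_brain(PhantomParams(infarct_fraction=0.1, seed=3))
bm = aggregate([measure_slice(img) for img in images])
print(compute_brain_metrics(bm))
```

For plate work, `triquant calibrate --plate plate.csv --tissue tissue.csv
--out report/` fits per-condition standard curves, converts sample
fluorescence to ng/g and, when several TTC conditions are present, emits
the interference table. `triquant compare --data groups.csv --out cmp.json`
runs the gated two-group comparison (Welch t vs Mann–Whitney U, routed by
a Lilliefors normality check and group size).

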