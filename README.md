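# pedct

Quantitative chest-CT densitometry for pediatric lungs, built as a reusable
pipeline with fully synthetic, ground-truthed test data:

- **`pedct.synthetic`** — phantom chest volumes (soft-tissue body, ellipsoidal
  lungs, exterior air) and synthetic cohorts. The parenchymal HU distribution
  is a calibrated two-component mixture (normal bulk + right-shifted
  exponential tail) that matches a target mean, SD, and the asymmetric
  fractions below/above (mean ± 1SD) observed in healthy aerated lung.
- **`pedct.segmentation`** — attenuation-window selection plus deterministic
  exterior-air removal (6-connected components touching a lateral grid face
  are discarded, as are sub-minimum components); central airways are kept.
- **`pedct.densitometry`** — per-subject statistics from width-1 integer-HU
  histograms: total lung volume (mL), mean/SD (population convention),
  subject-specific low/high attenuation thresholds (mean − 1SD / mean + 1SD),
  and the percent of lung volume strictly below/above them.
- **`pedct.reference`** — linear (`y = a + b·x`) and inverse/hyperbola
  (`y = a + b/x`) regression fits, Spearman rank correlations, and a built-in
  versioned reference-equation set (`pediatric_inspiratory_v1`) mapping age
  (6–17 y) or lung volume to each densitometry metric.
- **`pedct.reporting`** — cohort CSV I/O and summary tables by age group or
  500-mL volume bin in `median (P25, P75) (min, max)` format.

## CLI

Everything hangs off one umbrella command:

```sh
# synthetic phantom (NIfTI volume + ground-truth mask)
pedct simulate phantom --seed 1 --out phantom.nii.gz --out-mask gt.nii.gz

# synthetic cohort CSV drawn onto the reference curves
pedct simulate cohort --n 80 --seed 1 --noise-attenuation 35 --noise-tlc 450 \
    --noise-pct 1.5 --out cohort.csv

# segmentation and per-subject densitometry
pedct segment --in phantom.nii.gz --out-mask mask.nii.gz
pedct densitometry --in phantom.nii.gz --mask mask.nii.gz --out result.json

# model fitting, prediction from the built-in reference set, summary tables
pedct fit --in cohort.csv --response mean_hu --predictor age --form inverse
pedct predict --equation lat_vs_age --at 6 --round-hu 1
pedct report --in cohort.csv --by age
```

`pedct simulate phantom --config <json>` accepts a JSON object overriding any
phantom field (`grid_shape`, `spacing`, `lung_ellipsoids`,
`extra_air_pockets`, …) and a `distribution` block with calibration targets
(`mean`, `sd`, `frac_low`, `frac_high`).

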