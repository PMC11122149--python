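# circlemap

Circle-strategy analysis of high-density electroanatomic maps: local
conduction velocity (CV) and unipolar voltage amplitude (VA) estimation on
triangulated chamber surfaces, linear mixed-effects modelling of heart-rate
and pacing-location effects, and paired paced-vs-intrinsic map comparison.
Because high-density in-vivo recordings of all four chambers are rarely
shared, the package also ships a synthetic study generator that produces
chamber maps with the full statistical structure the analysis assumes, so
every stage is testable end to end without any data download.

## Who this is for

Cardiac electrophysiology researchers working with high-density
electroanatomic maps (thousands of measurement points per chamber, each
carrying a local activation time in ms and a unipolar amplitude in mV) who
want reproducible, scriptable local CV/VA statistics rather than
vendor-locked map displays — and statisticians who need a simulation bench
for mixed-model analyses of such maps.

## The method

**Local metrics by circle covering.** The curved map surface is covered with
spherical filters of radius *r* = 5 mm. For each circle the package
computes

- CV = 2*r* / (LAT_last − LAT_first), the theoretical diameter over the
  first-to-last activation interval inside the circle (mm/ms ≡ m/s), and
- VA = the arithmetic mean unipolar amplitude of the circle's points (mV).

For a planar wavefront at speed *v* crossing a flat circle this estimator is
exact (the interval is exactly 2*r*/*v*); for a focal (radial) wavefront it
can only overestimate. Velocities above 6 m/s are treated as outliers and
excluded (6.0 itself is kept); circles in cutout regions (vessel or valve
transitions) are never formed.

**Rate and location models.** Per-circle values enter linear mixed-effects
models

    log CV ~ heart_rate + group + (1 | animal)
    VA     ~ heart_rate + group + (1 | animal)

where `group` is the interaction of mapped chamber (or chamber wall) with
rhythm/pacing site, fitted by REML. The log-scale heart-rate coefficient
back-transforms to a multiplicative per-bpm CV effect
(CV = intercept × b^HR); the VA model gives an additive mV-per-bpm slope.
Group means are reported as estimated marginal means at a reference heart
rate (90 or 145 bpm) and paced-vs-NSR contrasts as CV ratios / VA
differences with Sidak- or Tukey-adjusted p-values.

**Paired local differences.** Circles of a paced map are matched to the
intrinsic-rhythm map of the same chamber and animal by mutual nearest
centers, and summarised by the mean of absolute differences, its IQR, the
absolute difference ratio (mean |Δ| / mean intrinsic), and the IQR of the
per-circle relative change.

## Worked example

Run the default synthetic study — 44 maps of the four chambers from four
animals under sinus rhythm and RA/LA/RV/LV pacing at 86–171 bpm, sampled at
~1.3 points/mm² — and read off the fitted effects:

```python
from circlemap import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(out_dir="results/demo", seed=1))
cv = bundle.cv_model.rate_effect()
va = bundle.va_model.rate_effect()
print(f"CV heart-rate effect: x{cv.cv_multiplier_per_bpm:.4f} per bpm")
print(f"VA heart-rate effect: {va.va_slope_mv_per_bpm:+.4f} mV per bpm")
```

prints, with the generator's default effect sizes:

```
maps analysed:        44
circles (modelling):  5711
CV heart-rate effect: x1.0038 per bpm (SE 0.0002)
VA heart-rate effect: -0.0125 mV per bpm (SE 0.0011)
RA paced vs NSR CV ratio at 145 bpm: 0.752 (95% CI 0.731-0.774, p_adj=0)
RV VA change under LV pacing at 145 bpm: +2.55 mV (95% CI +2.39-+2.71, p_adj=0)
```

That is: conduction speeds up by a factor ~1.004 per bpm of heart rate,
unipolar amplitude falls by ~0.012 mV per bpm, pacing the right atrium slows
RA conduction to ~0.75 of its sinus-rhythm value, and pacing the left
ventricle raises right-ventricular voltage by ~2.5 mV — each estimate
recovering the value the study was generated with. The bundle directory
holds the per-circle metrics, marginal means, contrasts and paired-difference
tables as CSV, figures, and a manifest with the seed and table hashes that
make the run bit-reproducible.

The same pipeline is available from the shell:

```bash
circlemap run --seed 1 --out results/run          # full pipeline
circlemap simulate --seed 1 --out results/maps    # just the synthetic maps
circlemap run --seed 1 --maps results/maps --out results/reanalysis
```

Maps are interchanged as binary PLY files with per-vertex arrays `lat_ms`,
`amplitude_mv`, `cutout`, `wall_id` plus a YAML metadata sidecar; any mesh
viewer opens the geometry.

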