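# viscsf

Toolkit for spatio-temporal contrast-sensitivity (CSF) modelling on modern
displays, and for using fitted CSF surfaces as perceptual weights in video
quality assessment.

What's inside:

- **stimulus** — synthesis of the circular Kaiser-windowed grating test
  pattern, its analytic spatial spectrum, and the flicker (PWM-envelope)
  temporal waveform.
- **display** — pixel-value → luminance calibration (gamma curve or
  measured LUT) and pixel-period ↔ cycles-per-degree geometry.
- **csf_models** — pluggable CSF surfaces: a complete 4th-order polynomial
  in normalized (spatial frequency, temporal frequency, background
  brightness), and the linear pyramid-of-visibility baseline. JSON
  serialization for externally fitted surfaces.
- **fitting** — exclusion filtering, per-condition aggregation,
  BT.500-style confidence intervals and the sequential stopping rule,
  ridge-regression surface fitting with an unpenalized intercept, and a
  log-linear flicker-slope analysis.
- **observer_sim** — synthetic-observer engine reproducing the two
  threshold-experiment designs (uniform-field flicker: 12 temporal × 5
  levels × 13 participants; spatio-temporal: 8 spatial × 12 temporal × 5
  levels × 2 stages × 29 participants) with lognormal threshold scatter,
  so the whole pipeline runs without measured data.
- **vqm** — CSF-weighted PSNR (frequency-domain error weighting), logistic
  mapping of metric scores to subjective scores, and PLCC with Fisher-z
  confidence bounds.

## CLI

All functionality is exposed through the `viscsf` entry point:

```sh
# render the test pattern
viscsf mira --width 1920 --height 1080 --diameter 790 --beta 6 \
    --period 40 --level 120 --amplitude 40 --out pattern.png

# simulate an experiment from a ground-truth surface
viscsf simulate --experiment 2 --truth pyramid.json --noise 0.05 \
    --seed 42 --out synthetic.csv

# fit the polynomial surface
viscsf fit --in synthetic.csv --order 4 --lambda 0.001 \
    --exclusions default --out model.json

# evaluate a surface at one point
viscsf eval --model model.json -k 3 -f 10 -l 120

# score a video pair and correlate with subjective scores
viscsf vqm --ref ref_frames/ --dist dist_frames/ --model model.json \
    --fps 25 --out scores.csv
viscsf correlate --scores scores.csv --mos mos.csv --out report.json

# full simulate -> fit -> evaluate pipeline from YAML
viscsf run --config demo_config.yaml

# write a small demo fixture set (truth model, config, tiny frames)
viscsf fixtures --out fixtures/
```

Exit codes: 0 success, 2 config error, 3 data error, 4 numerical failure.
Every pipeline artifact embeds the master seed and a hash of the
canonicalized config; identical config + seed reproduces byte-identical
outputs.

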