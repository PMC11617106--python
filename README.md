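# onesitebf

Validity analysis of one-site circumference body-fat equations against
laboratory criterion methods.

Military body composition screening estimates body fat percentage (BF%)
from sex-specific linear equations of the form

    BF% = b0 + b1 · mass + b2 · abdominal circumference

and flags soldiers above a service threshold. Whether such an equation
is *valid* is a method-comparison question: how do its BF%, fat mass
(FM) and fat-free mass (FFM) estimates agree with a 4-compartment (4C)
criterion model and with DXA? `onesitebf` packages that whole analysis
for researchers in body composition and military health:

- **equations** — sex-specific one-site equations with explicit unit
  handling, triplicate-scan averaging, FM/FFM derivation, and
  compliance classification against the DoD threshold bands
  (18–26% male, 26–36% female);
- **multicompartment** — the 4C model
  FM = 2.748·BV − 0.699·TBW + 1.129·Mo − 2.051·BM with the bone-mineral
  adjustment Mo = BMC/0.9582, and DXA-based estimates;
- **agreement** — the full validity panel: constant error (CE) ± SD,
  paired t, Pearson r/R², Lin's concordance correlation coefficient
  (CCC), SEE/RMSE/MAE, OLS of prediction on reference, Bland-Altman
  95% limits of agreement (CE ± 1.96·SD) and proportional-bias slope;
- **synthcohort** — a seeded synthetic cohort generator (default: 96
  subjects, 51 F / 45 M, age 23.7 ± 6.5 y, BMI 24.7 ± 4.1 kg/m²) whose
  latent truth satisfies the 4C equation exactly, plus a device-noise
  model and equation calibration;
- **pipeline / CLI** — end-to-end orchestration producing per-subject
  estimates, six agreement reports (BF%, FM, FFM × 4C, DXA), compliance
  summaries and Bland-Altman figures.

Official equation coefficients are not bundled: the packaged default is
an UNVERIFIED placeholder, and real use requires transcribing the
coefficients from the governing regulation (AR 600-9) into an
`EquationSpec` JSON. See `docs/methods.md` for model details and
conventions.

## Worked example

```
onesitebf run --seed 11 --out study_out
```

simulates the default cohort, calibrates a one-site equation on it,
computes the three estimates per subject and prints:

```
96 subjects analysed (0 dropped); outputs in study_out
  BF%  vs FOURC: CE -0.19 ± 3.21, MAE 2.64, CCC 0.906, LOA [-6.48, +6.11]
  BF%  vs DXA  : CE -1.16 ± 3.50, MAE 2.87, CCC 0.881, LOA [-8.02, +5.71]
  FM   vs FOURC: CE -0.13 ± 2.41, MAE 1.95, CCC 0.921, LOA [-4.86, +4.59]
  FM   vs DXA  : CE -0.82 ± 2.77, MAE 2.17, CCC 0.890, LOA [-6.25, +4.60]
  FFM  vs FOURC: CE +0.13 ± 2.41, MAE 1.95, CCC 0.984, LOA [-4.59, +4.86]
  FFM  vs DXA  : CE +0.82 ± 2.77, MAE 2.17, CCC 0.977, LOA [-4.60, +6.25]
```

Reading the first row: across 96 subjects the equation's BF% is
essentially unbiased against the 4C model on average (CE −0.19
percentage points, SD 3.21), misses by 2.6 points per subject (MAE),
and an individual's disagreement can plausibly span the ±6-point limits
of agreement. FM and FFM rows mirror each other exactly (same shared
body mass), and FFM shows higher CCC simply because FFM spans a wider
range. The equation here was calibrated against the latent truth the 4C
model tracks, so the DXA comparison inherits the simulated +1.2%
DXA offset. Per-subject estimates, report tables, compliance counts
(pass/flag per sex at the configured threshold) and figures land in
`study_out/`.

The same analysis runs on real data from a CSV with columns
`subject_id, sex, body_mass_kg, circ_scan1_cm..circ_scan3_cm,
body_volume_l, tbw_kg, dxa_bmc_kg, dxa_bf_percent`:

```
onesitebf estimate --input cohort.csv --equation my_equation.json
onesitebf compare --estimates estimates.csv
```

or in Python via `onesitebf.run_study(RunConfig(...))`.

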