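# Methods

## Problem

Military body composition programs screen soldiers by body fat
percentage (BF%) estimated from simple anthropometry. The current US
Army "one-site" approach predicts BF% from just two inputs — body mass
and an abdominal circumference at the navel — through sex-specific
linear equations. `onesitebf` implements the full validity analysis for
such an equation against two laboratory criterion methods: a
4-compartment (4C) model and dual-energy X-ray absorptiometry (DXA).
Because no participant-level dataset is publicly available for this
design, the package pairs the analysis engine with a synthetic cohort
generator so every stage is testable end to end.

## Models

### One-site equation

BF% = b0 + b1·mass + b2·circumference, with sex-specific coefficients.
Coefficients are configuration (`EquationSpec`), never code constants:
the official values live in service regulation tables (AR 600-9) and
must be transcribed by the user; the packaged default is an explicitly
UNVERIFIED placeholder. The spec declares its unit convention (kg/lb,
cm/in; conversions use the exact factors 2.54 cm/in and 0.45359237
kg/lb) and an optional nearest-half-unit rounding applied after
conversion, mirroring manual tape protocols. The default is no rounding:
digital anthropometry pipelines are continuous. Predictions outside
[0, 100)% are flagged and propagated unclipped — clipping would mask
exactly the tail behaviour (proportional bias) the analysis exists to
measure.

### 4-compartment model

FM = c_bv·BV + c_tbw·TBW + c_mo·Mo + c_bm·BM, with body volume BV (L)
from air displacement plethysmography, total body water TBW (kg) from
bioimpedance spectroscopy, osseous mineral Mo (kg) and body mass BM
(kg). Mo is derived from DXA bone mineral content as BMC / 0.9582
(ash-to-mineral conversion). Default coefficients are the published
Wang et al. (2002) values (2.748, −0.699, 1.129, −2.051), shipped as
configuration flagged for verification against the original source.
The same body mass (the ADP system's calibrated scale) feeds all three
methods; as a consequence FM and FFM constant errors are exact mirror
images, a structural identity the tests assert.

### Agreement engine

For each (outcome, reference) pair — outcomes BF%, FM, FFM; references
4C, DXA — the engine computes: constant error (mean of predicted −
reference) and its SD; a two-sided paired t test; Pearson r and R²;
Lin's concordance correlation coefficient; SEE, RMSE and MAE; the OLS
fit of prediction on reference; and a Bland-Altman analysis with 95%
limits of agreement and a proportional-bias regression.

Declared numerical conventions:

- Differences are predicted − reference, so overestimation by the
  equation appears as positive constant error.
- All variances/covariances use n−1 denominators, including inside the
  CCC. Lin's original formulation uses n; the discrepancy is O(1/n) and
  a single convention keeps every metric mutually exact.
- LOA multiplier is fixed at 1.96 (the conventional normal quantile),
  not a t quantile; this reproduces printed LOA from printed SDs.
- SEE is the regression standard error √(SS_res/(n−2)) from the
  reference→prediction OLS. The SD of raw differences is reported
  separately (`sd_diff`), so either reading of "standard error of the
  estimate" is available.
- Proportional bias regresses differences on the pairwise mean of the
  two methods (standard Bland-Altman); regression on the reference
  alone is available via `bias_regressor="reference"`.
- Two-sided p-values, no multiplicity correction. Normality is not
  gated; degenerate inputs (zero-variance vectors, constant
  differences) raise or flag rather than silently produce numbers.
  Identical vectors give t = 0, p = 1 by convention; a constant
  non-zero difference gives an infinite t and a `degenerate_t` flag.

## Synthetic cohort generator

The generator emulates a young-adult mixed-sex sample of 96
(51 F / 45 M; age 23.7 ± 6.5 y; BMI 24.7 ± 4.1 kg/m²) with a
truth-first design:

1. Draw age, stature (sex-specific: F 1.635 ± 0.065 m, M 1.766 ±
   0.071 m, conventional young-adult values) and BMI; mass = BMI·stature².
2. Draw true BF% (F 30 ± 6.5%, M 20 ± 6.5%, truncated to 3–55% by
   rejection); derive FM, FFM, TBW = 0.738·FFM (the conventional FFM
   hydration) and Mo = 0.052·FFM.
3. Solve the 4C equation for the single unknown BV at the true FM, so
   the criterion model is *exactly* consistent with the latent state by
   construction ("4C ≈ truth" is an axiom of the simulator, not an
   assumption).
4. Draw the true abdominal circumference from a linear model in mass
   and BF% (45 + 0.35·mass + 0.35·BF%, scatter SD 1.5 cm) — chosen so a
   calibrated two-input equation leaves a residual BF% SD of a few
   percentage points, the order reported for circumference equations
   against laboratory criteria.

Observation applies device noise: three circumference scans (SD 0.5 cm
each), BV (SD 0.15 L), TBW (SD 0.8 kg), BMC (SD 0.06 kg), DXA BF%
(SD 2.0%) plus a constant DXA bias (default +1.2%, representing the
systematic offset between laboratory methods). Body mass is observed
exactly. Non-positive or impossible draws are redrawn with a bounded
retry budget. One RNG stream per run, seeded explicitly; subject order
is stream order, so a seed fixes the cohort byte-for-byte.

Age is deliberately *not* truncated at 18 by default: truncating
N(23.7, 6.5) at 18 inflates the sample mean to ≈25.9 y, so the
untruncated draw is the one that reproduces the reported moments. Use
the rejection bounds in config where a hard floor matters.

`calibrate_equation` builds a self-consistent one-site equation by OLS
of *true* BF% on (mass, mean observed circumference) per sex — mimicking
how reference-method regression equations are developed — and packages
both sexes as a metric-unit `EquationSpec`.

### What the generator does not emulate

Real multivariate anthropometric covariance (stature–BMI–circumference
correlations fitted to survey data), skewed or heteroscedastic device
errors, scan-order drift, longitudinal change, and population-specific
equation bias. Passing tests therefore demonstrate the *pipeline's*
correctness (exact recovery under zero noise, correctly calibrated LOA
under known noise), not the field validity of any particular equation.

## Numerical and design choices

- Exact recovery tolerances: 1e-9 kg for the 4C inversion, 1e-8 for
  pipeline-level identities; both far below measurement resolution.
- The statistics engine routes t tests, correlation and OLS through
  scipy.stats; the test suite verifies every metric against independent
  brute-force formula evaluation (1 000 random vectors, agreement to
  1e-10).
- Truncation rejection is warned about when it exceeds 1% of draws
  (with at least 3 rejections, to avoid noise on small cohorts).
- Compliance classification is boundary-inclusive (BF% equal to the
  service threshold passes) and the service threshold must lie inside
  the directive band (18–26% M, 26–36% F); anything else is a hard
  error naming the band.
- Input CSV rows failing plausibility (mass outside 30–250 kg,
  circumference outside 40–200 cm) are retained with warnings; hard
  schema or sign errors drop the row; more than 20% dropped aborts the
  run.
- Problem sizes in the test suite: noiseless recovery at the study's
  n 96; noise-calibration checks at n 10 000 (Monte-Carlo error ~1%);
  proportional-bias detection at n 500.

## Known limitations

Packaged equation coefficients are placeholders until transcribed from
the regulation; the Wang coefficients should be verified against the
original publication; the generator's DXA error model is a constant
bias plus iid Gaussian noise, whereas real DXA–4C discrepancies vary
with fatness and hydration; and n−1 CCC differs from Lin's n-denominator
CCC by O(1/n) (≈0.5% at n 96) — comparisons against software using the
n convention should expect that gap at small n.
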