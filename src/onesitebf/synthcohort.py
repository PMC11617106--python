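"""Synthetic cohort generator for end-to-end pipeline testing.

No participant-level data accompany the validity study this package
models, so testing requires a simulator that produces physiologically
coherent cohorts: a latent "truth" per subject (body mass, true BF%, and
the water, mineral and volume compartments consistent with it) plus
noisy device observations (triplicate optical circumference scans, ADP
body volume, BIS total body water, DXA bone mineral content and BF%).

Truth-first design: true fat mass, total body water (hydration fraction
of FFM) and osseous mineral (mineral fraction of FFM) are drawn or
derived first, and body volume is then obtained by algebraically
inverting the 4-compartment fat-mass equation.  The criterion model is
therefore *exactly* consistent with the latent state — with zero device
noise the 4C stage recovers true fat mass to numerical precision, which
is the basis of the parameter-recovery tests.

Default demographics mirror a young-adult sample of 96 (51 F / 45 M,
age 23.7 +/- 6.5 y, BMI 24.7 +/- 4.1 kg/m^2); everything is configurable
through :class:`CohortConfig`.  A single RNG stream, seeded explicitly,
drives each run; subject order is the stream order, so identical seeds
give byte-identical cohort tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from onesitebf.equations import EquationSpec
from onesitebf.multicompartment import (
    BMC_TO_MINERAL_DIVISOR,
    DeviceMeasurements,
    WangCoefficients,
)

__all__ = [
    "CohortConfig",
    "ParticipantRecord",
    "TrueState",
    "calibrate_equation",
    "calibrate_one_site_equation",
    "generate_truth",
    "observe",
    "observe_cohort",
    "simulate_cohort",
    "truth_to_frame",
]

OBSERVED_COLUMNS = [
    "subject_id",
    "sex",
    "body_mass_kg",
    "circ_scan1_cm",
    "circ_scan2_cm",
    "circ_scan3_cm",
    "body_volume_l",
    "tbw_kg",
    "dxa_bmc_kg",
    "dxa_bf_percent",
]


class CohortConfig(BaseModel):
    """Distributions, physiological fractions, device-noise SDs and seed.

    Sample-size and demographic defaults reproduce the modelled study
    sample; noise SDs are typical short-term device precisions;
    ``dxa_bias`` is a constant offset of DXA BF% relative to the latent
    truth (criterion methods disagree systematically in practice).
    """

    n_total: int = 96
    n_female: int = 51
    n_male: int = 45

    age_mean: float = 23.7
    age_sd: float = 6.5

    bmi_mean: float = 24.7
    bmi_sd: float = 4.1

    stature_mean_female: float = 1.635
    stature_sd_female: float = 0.065
    stature_mean_male: float = 1.766
    stature_sd_male: float = 0.071

    bf_mean_female: float = 30.0
    bf_sd_female: float = 6.5
    bf_mean_male: float = 20.0
    bf_sd_male: float = 6.5
    bf_min: float = 3.0
    bf_max: float = 55.0

    hydration_of_ffm: float = 0.738
    mineral_fraction_of_ffm: float = 0.052

    # abdominal circumference (cm) ~ intercept + per_kg*mass + per_bf*BF% + scatter
    circ_intercept_cm: float = 45.0
    circ_per_kg: float = 0.35
    circ_per_bf_pct: float = 0.35
    circ_scatter_sd: float = 1.5

    circ_scan_sd: float = 0.5
    bv_sd: float = 0.15
    tbw_sd: float = 0.8
    bmc_sd: float = 0.06
    dxa_bf_sd: float = 2.0
    dxa_bias: float = 1.2

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if self.n_female + self.n_male != self.n_total:
            raise ValueError("n_female + n_male must equal n_total")
        for name in ("circ_scatter_sd", "circ_scan_sd", "bv_sd", "tbw_sd",
                     "bmc_sd", "dxa_bf_sd", "age_sd", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("hydration_of_ffm", "mineral_fraction_of_ffm"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not (0.0 <= self.bf_min < self.bf_max < 100.0):
            raise ValueError("require 0 <= bf_min < bf_max < 100")
        return self

    def noiseless(self) -> "CohortConfig":
        """Copy with every observation noise SD, the circumference scatter
        and the DXA bias set to zero (latent truth passes through the
        devices unchanged)."""
        return self.model_copy(
            update=dict(
                circ_scatter_sd=0.0, circ_scan_sd=0.0, bv_sd=0.0,
                tbw_sd=0.0, bmc_sd=0.0, dxa_bf_sd=0.0, dxa_bias=0.0,
            )
        )


@dataclass(frozen=True)
class TrueState:
    """Latent truth for one simulated subject."""

    subject_id: str
    sex: str
    age: float
    stature_m: float
    body_mass_kg: float
    true_bf_percent: float
    true_fm_kg: float
    true_ffm_kg: float
    true_tbw_kg: float
    true_mo_kg: float
    true_bv_l: float
    true_abdomen_circ_cm: float


@dataclass(frozen=True)
class ParticipantRecord:
    """Observable anthropometric record: body mass plus replicate scans."""

    subject_id: str
    sex: str
    body_mass_kg: float
    circ_scans_cm: tuple[float, ...]


class _TruncatedDraw:
    """Rejection sampler on a shared stream, counting rejections."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.attempts = 0
        self.rejections = 0

    def normal(
        self,
        mean: float,
        sd: float,
        low: float = -np.inf,
        high: float = np.inf,
        max_tries: int = 1000,
    ) -> float:
        for _ in range(max_tries):
            self.attempts += 1
            x = float(self.rng.normal(mean, sd))
            if low < x < high:
                return x
            self.rejections += 1
        raise RuntimeError(
            f"truncated draw N({mean}, {sd}) on ({low}, {high}) failed "
            f"after {max_tries} tries"
        )


def generate_truth(
    config: CohortConfig,
    coeffs: WangCoefficients | None = None,
    rng: np.random.Generator | None = None,
) -> list[TrueState]:
    """Draw the latent cohort: females first, then males, in stream order.

    Body mass follows from BMI and stature; water and mineral follow
    from FFM via the configured fractions; body volume is the unique
    solution of the 4C fat-mass equation at the true fat mass.
    """
    coeffs = coeffs or WangCoefficients()
    if coeffs.c_bv == 0:
        raise ValueError("cannot invert the 4C equation with c_bv == 0")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    draw = _TruncatedDraw(rng)

    subjects: list[TrueState] = []
    sexes = ["F"] * config.n_female + ["M"] * config.n_male
    for i, sex in enumerate(sexes):
        if sex == "F":
            st_mean, st_sd = config.stature_mean_female, config.stature_sd_female
            bf_mean, bf_sd = config.bf_mean_female, config.bf_sd_female
        else:
            st_mean, st_sd = config.stature_mean_male, config.stature_sd_male
            bf_mean, bf_sd = config.bf_mean_male, config.bf_sd_male

        age = draw.normal(config.age_mean, config.age_sd)
        stature = draw.normal(st_mean, st_sd, low=0.0)
        bmi = draw.normal(config.bmi_mean, config.bmi_sd, low=0.0)
        mass = bmi * stature * stature
        bf = draw.normal(bf_mean, bf_sd, low=config.bf_min, high=config.bf_max)

        fm = bf / 100.0 * mass
        ffm = mass - fm
        tbw = config.hydration_of_ffm * ffm
        mo = config.mineral_fraction_of_ffm * ffm
        bv = (fm - coeffs.c_tbw * tbw - coeffs.c_mo * mo - coeffs.c_bm * mass) / coeffs.c_bv
        circ = (
            config.circ_intercept_cm
            + config.circ_per_kg * mass
            + config.circ_per_bf_pct * bf
            + float(rng.normal(0.0, config.circ_scatter_sd))
        )
        subjects.append(
            TrueState(
                subject_id=f"S{i + 1:03d}",
                sex=sex,
                age=age,
                stature_m=stature,
                body_mass_kg=mass,
                true_bf_percent=bf,
                true_fm_kg=fm,
                true_ffm_kg=ffm,
                true_tbw_kg=tbw,
                true_mo_kg=mo,
                true_bv_l=bv,
                true_abdomen_circ_cm=circ,
            )
        )

    if draw.rejections >= 3 and draw.rejections / draw.attempts > 0.01:
        warnings.warn(
            f"truncation rejected {draw.rejections} of {draw.attempts} draws "
            "(> 1%); configured SDs sit close to the truncation bounds",
            stacklevel=2,
        )
    return subjects


def _positive_draw(
    rng: np.random.Generator, center: float, sd: float, upper: float = np.inf,
    max_tries: int = 100,
) -> float:
    for _ in range(max_tries):
        x = float(rng.normal(center, sd))
        if 0.0 < x < upper:
            return x
    raise RuntimeError(
        f"observation N({center}, {sd}) failed to land in (0, {upper}) "
        f"after {max_tries} redraws"
    )


def observe(
    truth: TrueState,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ParticipantRecord, DeviceMeasurements]:
    """Pass one subject's truth through the device-noise model.

    Three circumference scans get iid Gaussian noise; BV, TBW and BMC
    get their device noise; DXA BF% gets the configured bias plus noise;
    body mass is observed exactly (scale noise is negligible at this
    resolution).  Non-positive or physiologically impossible draws are
    redrawn with a bounded retry budget.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    scans = tuple(
        _positive_draw(rng, truth.true_abdomen_circ_cm, config.circ_scan_sd)
        for _ in range(3)
    )
    mass = truth.body_mass_kg
    bv = _positive_draw(rng, truth.true_bv_l, config.bv_sd)
    tbw = _positive_draw(rng, truth.true_tbw_kg, config.tbw_sd, upper=mass)
    bmc_true = truth.true_mo_kg * BMC_TO_MINERAL_DIVISOR
    bmc = _positive_draw(rng, bmc_true, config.bmc_sd, upper=mass)
    dxa_bf = _positive_draw(
        rng, truth.true_bf_percent + config.dxa_bias, config.dxa_bf_sd, upper=100.0
    )
    record = ParticipantRecord(
        subject_id=truth.subject_id,
        sex=truth.sex,
        body_mass_kg=mass,
        circ_scans_cm=scans,
    )
    meas = DeviceMeasurements(
        subject_id=truth.subject_id,
        body_mass_kg=mass,
        body_volume_l=bv,
        tbw_kg=tbw,
        dxa_bmc_kg=bmc,
        dxa_bf_percent=dxa_bf,
    )
    return record, meas


def observe_cohort(
    truths: list[TrueState],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed cohort table in the pipeline's CSV schema."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows = []
    for truth in truths:
        rec, meas = observe(truth, config, rng)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "sex": rec.sex,
                "body_mass_kg": rec.body_mass_kg,
                "circ_scan1_cm": rec.circ_scans_cm[0],
                "circ_scan2_cm": rec.circ_scans_cm[1],
                "circ_scan3_cm": rec.circ_scans_cm[2],
                "body_volume_l": meas.body_volume_l,
                "tbw_kg": meas.tbw_kg,
                "dxa_bmc_kg": meas.dxa_bmc_kg,
                "dxa_bf_percent": meas.dxa_bf_percent,
            }
        )
    return pd.DataFrame(rows, columns=OBSERVED_COLUMNS)


def truth_to_frame(truths: list[TrueState]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truths])


def simulate_cohort(
    config: CohortConfig,
    coeffs: WangCoefficients | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(truth table, observed table) from a single seeded RNG stream."""
    rng = np.random.default_rng(config.seed)
    truths = generate_truth(config, coeffs, rng=rng)
    observed = observe_cohort(truths, config, rng=rng)
    return truth_to_frame(truths), observed


def calibrate_equation(
    truth_df: pd.DataFrame,
    observed_df: pd.DataFrame,
    sex: str,
) -> tuple[float, float, float]:
    """Fit a one-site equation for one sex by OLS of true BF% on
    (body mass, mean observed circumference).

    Mimics how reference-method regression equations are built: the
    latent BF% plays the criterion role.  Returns (intercept, mass
    coefficient, circumference coefficient) in metric units.
    """
    merged = truth_df.merge(observed_df, on="subject_id", suffixes=("", "_obs"))
    sub = merged[merged["sex"] == sex]
    if len(sub) < 20:
        raise ValueError(
            f"need at least 20 subjects of sex {sex!r} to calibrate, got {len(sub)}"
        )
    circ = sub[["circ_scan1_cm", "circ_scan2_cm", "circ_scan3_cm"]].mean(axis=1)
    X = np.column_stack(
        [np.ones(len(sub)), sub["body_mass_kg"].to_numpy(), circ.to_numpy()]
    )
    y = sub["true_bf_percent"].to_numpy()
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("collinear predictors: mass and circumference are "
                         "linearly dependent in this cohort")
    return float(coef[0]), float(coef[1]), float(coef[2])


def calibrate_one_site_equation(
    truth_df: pd.DataFrame,
    observed_df: pd.DataFrame,
    name: str = "calibrated-synthetic",
) -> EquationSpec:
    """Sex-specific calibrated equation packaged as an :class:`EquationSpec`."""
    b0_f, b1_f, b2_f = calibrate_equation(truth_df, observed_df, "F")
    b0_m, b1_m, b2_m = calibrate_equation(truth_df, observed_df, "M")
    return EquationSpec(
        name=name,
        intercept_male=b0_m,
        coef_mass_male=b1_m,
        coef_circ_male=b2_m,
        intercept_female=b0_f,
        coef_mass_female=b1_f,
        coef_circ_female=b2_f,
        mass_unit="kg",
        circ_unit="cm",
        rounding_rule="none",
        verified=True,
    )
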