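"""Method-comparison statistics for paired body-composition estimates.

Given paired vectors of a predicted outcome (the circumference equation)
and a reference outcome (4C or DXA), this module computes the standard
validity panel: constant error (mean difference) with its SD, a paired
t test, Pearson r and R^2, Lin's concordance correlation coefficient,
SEE / RMSE / MAE, an ordinary least squares fit of prediction on
reference, and a Bland-Altman analysis with 95% limits of agreement and
a proportional-bias regression.

Conventions (documented, applied uniformly):

* Differences are predicted - reference, so a method that overestimates
  shows a positive constant error.
* All variances and covariances use the n-1 (sample) denominator,
  including inside the CCC.  Lin's original formulation uses n; the
  difference vanishes as n grows and declaring one convention keeps
  every metric exactly consistent.
* Limits of agreement use the fixed 1.96 normal multiplier, not a t
  quantile.
* SEE is the regression standard error sqrt(SS_res / (n-2)) from the
  reference -> prediction OLS; the SD of raw differences is available
  separately as ``sd_diff``.
* Proportional bias regresses differences on the pairwise mean of the
  two methods (standard Bland-Altman); regression on the reference
  alone is available via ``bias_regressor="reference"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "LOA_MULTIPLIER",
    "PairedSample",
    "bland_altman",
    "constant_error",
    "correlation_metrics",
    "error_metrics",
    "full_report",
    "lin_ccc",
    "ols_fit",
    "paired_t_test",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedSample:
    """Paired predicted/reference vectors for one outcome.

    ``predicted`` is the equation under evaluation (the regression y);
    ``reference`` is the criterion method (the regression x).
    """

    predicted: np.ndarray
    reference: np.ndarray
    outcome_label: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.predicted, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        object.__setattr__(self, "predicted", p)
        object.__setattr__(self, "reference", r)
        if p.ndim != 1 or r.ndim != 1:
            raise ValueError("predicted and reference must be 1-D vectors")
        if p.shape != r.shape:
            raise ValueError(
                f"length mismatch: predicted {p.size}, reference {r.size}"
            )
        if p.size < 3:
            raise ValueError(f"need at least 3 pairs, got {p.size}")
        if np.isnan(p).any() or np.isnan(r).any():
            raise ValueError("missing values must be removed before pairing")

    @property
    def n(self) -> int:
        return int(self.predicted.size)

    @property
    def differences(self) -> np.ndarray:
        return self.predicted - self.reference

    @property
    def means(self) -> np.ndarray:
        return (self.predicted + self.reference) / 2.0

    def swapped(self) -> "PairedSample":
        return PairedSample(self.reference, self.predicted, self.outcome_label)


@dataclass(frozen=True)
class AgreementReport:
    """Complete validity panel for one (prediction, reference, outcome) triple."""

    outcome_label: str
    n: int
    constant_error: float
    sd_diff: float
    t_stat: float
    p_value: float
    df: int
    pearson_r: float
    r_squared: float
    ccc: float
    see: float
    rmse: float
    mae: float
    loa_lower: float
    loa_upper: float
    loa_half_width: float
    ba_slope: float
    ba_intercept: float
    ba_slope_p: float
    ols_slope: float
    ols_intercept: float
    flags: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8"
        )


def constant_error(s: PairedSample) -> tuple[float, float]:
    """Mean and sample SD (n-1) of the predicted - reference differences."""
    d = s.differences
    if d.size < 2:
        raise ValueError("need at least 2 pairs for a difference SD")
    return float(np.mean(d)), float(np.std(d, ddof=1))


def paired_t_test(s: PairedSample) -> tuple[float, float, int]:
    """Two-sided paired t test of mean difference zero.

    Degenerate cases: identical vectors (sd_diff 0, mean 0) give t = 0,
    p = 1 by convention; a constant non-zero difference gives an
    infinite t and p = 0 (the caller sees the ``degenerate_t`` flag via
    :func:`full_report`).
    """
    d = s.differences
    n = d.size
    ce = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if ce == 0.0:
            return 0.0, 1.0, n - 1
        return math.copysign(math.inf, ce), 0.0, n - 1
    res = stats.ttest_rel(s.predicted, s.reference)
    return float(res.statistic), float(res.pvalue), int(res.df)


def correlation_metrics(s: PairedSample) -> tuple[float, float]:
    """Pearson product-moment r and R^2; zero variance is an error."""
    if np.std(s.predicted) == 0 or np.std(s.reference) == 0:
        raise ValueError("correlation undefined: a vector is constant")
    r = float(stats.pearsonr(s.reference, s.predicted).statistic)
    return r, r * r


def lin_ccc(s: PairedSample) -> float:
    """Lin's concordance correlation coefficient.

    ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)

    with n-1 denominators throughout (see module conventions).  It
    penalises both dispersion and location shift relative to the
    identity line, so |ccc| <= |r| always.
    """
    x = s.reference
    y = s.predicted
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("CCC undefined: a vector is constant")
    cov = float(np.cov(x, y, ddof=1)[0, 1])
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    shift = float(np.mean(x) - np.mean(y))
    return 2.0 * cov / (vx + vy + shift * shift)


def error_metrics(s: PairedSample) -> tuple[float, float, float]:
    """(SEE, RMSE, MAE).

    RMSE and MAE summarise the raw differences; SEE is the residual
    standard error of the reference -> prediction OLS, sqrt(SS_res/(n-2)).
    """
    d = s.differences
    rmse = float(np.sqrt(np.mean(d * d)))
    mae = float(np.mean(np.abs(d)))
    slope, intercept = _ols(s)
    resid = s.predicted - (intercept + slope * s.reference)
    see = float(np.sqrt(np.sum(resid * resid) / (s.n - 2)))
    return see, rmse, mae


def _ols(s: PairedSample) -> tuple[float, float]:
    if np.std(s.reference) == 0:
        raise ValueError("OLS undefined: reference is constant")
    res = stats.linregress(s.reference, s.predicted)
    return float(res.slope), float(res.intercept)


def ols_fit(s: PairedSample) -> tuple[float, float, np.ndarray]:
    """OLS of prediction on reference: (slope, intercept, residuals)."""
    slope, intercept = _ols(s)
    residuals = s.predicted - (intercept + slope * s.reference)
    return slope, intercept, residuals


def bland_altman(
    s: PairedSample,
    bias_regressor: Literal["mean", "reference"] = "mean",
) -> tuple[float, float, float, float, float]:
    """Bland-Altman limits of agreement and proportional-bias regression.

    Returns (loa_lower, loa_upper, ba_slope, ba_intercept, ba_slope_p).
    LOA = CE +/- 1.96 * SD(differences).  Proportional bias is the OLS
    slope of differences on the pairwise mean of the two methods (or on
    the reference alone, if requested); its two-sided p-value tests a
    zero slope.
    """
    ce, sd = constant_error(s)
    lo = ce - LOA_MULTIPLIER * sd
    hi = ce + LOA_MULTIPLIER * sd
    x = s.means if bias_regressor == "mean" else s.reference
    d = s.differences
    if np.std(x) == 0:
        raise ValueError("proportional-bias slope undefined: regressor is constant")
    if np.std(d) == 0.0:
        # perfectly constant differences: zero slope, no evidence of trend
        return lo, hi, 0.0, float(d[0]), 1.0
    res = stats.linregress(x, d)
    return lo, hi, float(res.slope), float(res.intercept), float(res.pvalue)


def full_report(
    s: PairedSample,
    bias_regressor: Literal["mean", "reference"] = "mean",
) -> AgreementReport:
    """Assemble the complete validity panel for one paired sample."""
    ce, sd = constant_error(s)
    t, p, df = paired_t_test(s)
    r, r2 = correlation_metrics(s)
    ccc = lin_ccc(s)
    see, rmse, mae = error_metrics(s)
    lo, hi, ba_slope, ba_int, ba_p = bland_altman(s, bias_regressor)
    slope, intercept, _ = ols_fit(s)
    flags: list[str] = []
    if sd == 0.0 and ce != 0.0:
        flags.append("degenerate_t")
    return AgreementReport(
        outcome_label=s.outcome_label,
        n=s.n,
        constant_error=ce,
        sd_diff=sd,
        t_stat=t,
        p_value=p,
        df=df,
        pearson_r=r,
        r_squared=r2,
        ccc=ccc,
        see=see,
        rmse=rmse,
        mae=mae,
        loa_lower=lo,
        loa_upper=hi,
        loa_half_width=LOA_MULTIPLIER * sd,
        ba_slope=ba_slope,
        ba_intercept=ba_int,
        ba_slope_p=ba_p,
        ols_slope=slope,
        ols_intercept=intercept,
        flags=tuple(flags),
    )
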