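"""Brute-force reference formulas for the agreement metrics.

Everything here is computed from explicit sums, independently of the
library code paths under test (which route through scipy's statistical
routines); only distribution CDFs are taken from scipy.  Used to verify
oracle equivalence on random vectors.
"""

from __future__ import annotations

import math

from scipy.stats import t as t_dist


def _mean(v):
    return sum(v) / len(v)


def _sum_sq(v, m):
    return sum((x - m) ** 2 for x in v)


def brute_force_metrics(pred, ref):
    """Full metric panel via direct formula evaluation (n-1 denominators)."""
    n = len(pred)
    d = [p - r for p, r in zip(pred, ref)]
    ce = _mean(d)
    sd = math.sqrt(_sum_sq(d, ce) / (n - 1))

    if sd == 0:
        t_stat, p_val = (0.0, 1.0) if ce == 0 else (math.copysign(math.inf, ce), 0.0)
    else:
        t_stat = ce / (sd / math.sqrt(n))
        p_val = 2 * t_dist.sf(abs(t_stat), n - 1)

    mx, my = _mean(ref), _mean(pred)
    sxx = _sum_sq(ref, mx) / (n - 1)
    syy = _sum_sq(pred, my) / (n - 1)
    sxy = sum((x - mx) * (y - my) for x, y in zip(ref, pred)) / (n - 1)
    r = sxy / math.sqrt(sxx * syy)
    ccc = 2 * sxy / (sxx + syy + (mx - my) ** 2)

    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((y - intercept - slope * x) ** 2 for x, y in zip(ref, pred))
    see = math.sqrt(ss_res / (n - 2))
    rmse = math.sqrt(sum(x * x for x in d) / n)
    mae = _mean([abs(x) for x in d])

    loa_lower = ce - 1.96 * sd
    loa_upper = ce + 1.96 * sd

    means = [(p + r) / 2 for p, r in zip(pred, ref)]
    mm = _mean(means)
    smm = _sum_sq(means, mm) / (n - 1)
    smd = sum((m - mm) * (di - ce) for m, di in zip(means, d)) / (n - 1)
    if sd == 0:
        ba_slope, ba_intercept, ba_p = 0.0, d[0], 1.0
    else:
        ba_slope = smd / smm
        ba_intercept = ce - ba_slope * mm
        ss_res_ba = sum(
            (di - ba_intercept - ba_slope * m) ** 2 for m, di in zip(means, d)
        )
        se_slope = math.sqrt(ss_res_ba / (n - 2) / ((n - 1) * smm))
        tt = ba_slope / se_slope
        ba_p = 2 * t_dist.sf(abs(tt), n - 2)

    return {
        "constant_error": ce,
        "sd_diff": sd,
        "t_stat": t_stat,
        "p_value": p_val,
        "pearson_r": r,
        "r_squared": r * r,
        "ccc": ccc,
        "see": see,
        "rmse": rmse,
        "mae": mae,
        "loa_lower": loa_lower,
        "loa_upper": loa_upper,
        "loa_half_width": 1.96 * sd,
        "ba_slope": ba_slope,
        "ba_intercept": ba_intercept,
        "ba_slope_p": ba_p,
        "ols_slope": slope,
        "ols_intercept": intercept,
    }
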