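"""End-to-end orchestration: cohort in, Table-style validity reports out.

`run_study` ingests (or simulates) a cohort, computes the three
composition estimates per subject — one-site equation, 4-compartment
model, DXA — and produces the six agreement reports (BF%, FM, FFM, each
against 4C and against DXA), a per-sex compliance summary, and optional
scatter / Bland-Altman figure files.  Estimates and reports are written
as separate CSVs so the agreement engine can be reused on externally
produced estimate tables.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from onesitebf.agreement import AgreementReport, PairedSample, full_report
from onesitebf.equations import (
    ComplianceThresholds,
    CompositionEstimate,
    EquationSpec,
    MissingScanWarning,
    average_scan_circumferences,
    bf_to_composition,
    classify_compliance,
    default_equation_spec,
    normalize_sex,
    one_site_bf_percent,
)
from onesitebf.multicompartment import (
    DeviceMeasurements,
    WangCoefficients,
    dxa_composition,
    four_c_composition,
)
from onesitebf.synthcohort import (
    OBSERVED_COLUMNS,
    CohortConfig,
    calibrate_one_site_equation,
    simulate_cohort,
)

__all__ = [
    "OUTCOMES",
    "REFERENCES",
    "RunConfig",
    "StudyResult",
    "run_study",
    "validate_input",
]

logger = logging.getLogger("onesitebf")

OUTCOMES = ("BF%", "FM", "FFM")
REFERENCES = ("FOURC", "DXA")

_OUTCOME_COLUMNS = {"BF%": "bf_percent", "FM": "fat_mass_kg", "FFM": "ffm_kg"}

REQUIRED_COLUMNS = OBSERVED_COLUMNS

# plausibility bounds used by validate_input (warnings, not drops)
MASS_BOUNDS_KG = (30.0, 250.0)
CIRC_BOUNDS_CM = (40.0, 200.0)


class RunConfig(BaseModel):
    """One study run: input mode, model configuration, outputs, seed."""

    mode: Literal["csv", "simulate"]
    input_csv: Optional[Path] = None
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    equation_json: Optional[Path] = None
    wang_json: Optional[Path] = None
    thresholds: ComplianceThresholds = Field(default_factory=ComplianceThresholds)
    service_threshold_male: Optional[float] = None
    service_threshold_female: Optional[float] = None
    out_dir: Path = Path("study_out")
    plots: bool = False
    write_truth: bool = True
    log_level: str = "INFO"
    seed: int = 0

    model_config = {"arbitrary_types_allowed": True}

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.mode == "csv":
            if self.input_csv is None:
                raise ValueError("csv mode requires input_csv")
            if not Path(self.input_csv).exists():
                raise FileNotFoundError(f"input CSV not found: {self.input_csv}")
        for p in (self.equation_json, self.wang_json):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config file not found: {p}")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))


@dataclass
class StudyResult:
    """In-memory results of one run, alongside the files on disk."""

    estimates: pd.DataFrame
    reports: dict[tuple[str, str], AgreementReport]
    compliance: pd.DataFrame
    n_subjects: int
    n_dropped: int
    flagged: list[dict]
    out_dir: Path

    def report(self, outcome: str, reference: str) -> AgreementReport:
        return self.reports[(outcome, reference)]


def validate_input(csv_path: str | Path) -> list[dict]:
    """Machine-readable schema and plausibility issues for an input CSV.

    Each issue is ``{"row": index or None, "column": name or None,
    "severity": "error"|"warning", "message": str}``; schema errors have
    ``row`` None.  Plausibility findings (mass outside 30-250 kg,
    circumference outside 40-200 cm) are warnings — the row is retained.
    """
    path = Path(csv_path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty input file: {path}")

    issues: list[dict] = []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            issues.append(
                {"row": None, "column": col, "severity": "error",
                 "message": f"missing required column {col!r}"}
            )
    if any(i["severity"] == "error" for i in issues):
        return issues

    circ_cols = ["circ_scan1_cm", "circ_scan2_cm", "circ_scan3_cm"]
    for idx, row in df.iterrows():
        try:
            normalize_sex(row["sex"])
        except ValueError:
            issues.append({"row": int(idx), "column": "sex", "severity": "error",
                           "message": f"unrecognised sex code {row['sex']!r}"})
        mass = row["body_mass_kg"]
        if pd.isna(mass) or mass <= 0:
            issues.append({"row": int(idx), "column": "body_mass_kg",
                           "severity": "error",
                           "message": f"non-positive or missing body mass: {mass}"})
        elif not (MASS_BOUNDS_KG[0] <= mass <= MASS_BOUNDS_KG[1]):
            issues.append({"row": int(idx), "column": "body_mass_kg",
                           "severity": "warning",
                           "message": f"body mass {mass} kg outside plausible "
                                      f"range {MASS_BOUNDS_KG}; row retained"})
        for col in circ_cols:
            c = row[col]
            if pd.isna(c):
                continue  # missing scans are tolerated; averaging warns
            if c <= 0:
                issues.append({"row": int(idx), "column": col, "severity": "error",
                               "message": f"non-positive circumference: {c}"})
            elif not (CIRC_BOUNDS_CM[0] <= c <= CIRC_BOUNDS_CM[1]):
                issues.append({"row": int(idx), "column": col,
                               "severity": "warning",
                               "message": f"circumference {c} cm outside plausible "
                                          f"range {CIRC_BOUNDS_CM}; row retained"})
        for col in ("body_volume_l", "tbw_kg", "dxa_bmc_kg", "dxa_bf_percent"):
            v = row[col]
            if not pd.isna(v) and v <= 0:
                issues.append({"row": int(idx), "column": col, "severity": "error",
                               "message": f"non-positive {col}: {v}"})
    return issues


def _subject_estimates(
    row: pd.Series, spec: EquationSpec, coeffs: WangCoefficients
) -> list[CompositionEstimate]:
    sid = str(row["subject_id"])
    sex = normalize_sex(row["sex"])
    mass = float(row["body_mass_kg"])
    scans = [
        float(row[c])
        for c in ("circ_scan1_cm", "circ_scan2_cm", "circ_scan3_cm")
        if not pd.isna(row[c])
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingScanWarning)
        circ = average_scan_circumferences(scans)
        if len(scans) < 3:
            logger.warning("subject %s: only %d circumference scans", sid, len(scans))
    army_bf = one_site_bf_percent(sex, mass, circ, spec)
    army = bf_to_composition(sid, "ARMY1", army_bf, mass)
    meas = DeviceMeasurements(
        subject_id=sid,
        body_mass_kg=mass,
        body_volume_l=float(row["body_volume_l"]),
        tbw_kg=float(row["tbw_kg"]),
        dxa_bmc_kg=float(row["dxa_bmc_kg"]),
        dxa_bf_percent=float(row["dxa_bf_percent"]),
    )
    fourc = four_c_composition(meas, coeffs)
    dxa = dxa_composition(sid, float(row["dxa_bf_percent"]), mass)
    return [army, fourc, dxa]


def _estimates_frame(
    cohort: pd.DataFrame, spec: EquationSpec, coeffs: WangCoefficients
) -> tuple[pd.DataFrame, list[dict], int]:
    rows, flagged = [], []
    n_dropped = 0
    for _, row in cohort.iterrows():
        required = [row[c] for c in REQUIRED_COLUMNS if not c.startswith("circ_")]
        scans = [row[c] for c in REQUIRED_COLUMNS if c.startswith("circ_")]
        if any(pd.isna(v) for v in required) or all(pd.isna(v) for v in scans):
            n_dropped += 1
            logger.warning("dropping subject %s: missing required fields",
                           row.get("subject_id"))
            continue
        try:
            estimates = _subject_estimates(row, spec, coeffs)
        except (ValueError, KeyError) as exc:
            n_dropped += 1
            logger.warning("dropping subject %s: %s", row.get("subject_id"), exc)
            continue
        for est in estimates:
            if est.flags:
                flagged.append(
                    {"subject_id": est.subject_id, "method": est.method,
                     "flags": list(est.flags)}
                )
                logger.warning("subject %s [%s]: %s", est.subject_id,
                               est.method, ", ".join(est.flags))
            rows.append(
                {"subject_id": est.subject_id,
                 "sex": normalize_sex(row["sex"]),
                 "method": est.method,
                 "body_mass_kg": est.body_mass_kg,
                 "bf_percent": est.bf_percent,
                 "fat_mass_kg": est.fat_mass_kg,
                 "ffm_kg": est.ffm_kg,
                 "flags": ";".join(est.flags)}
            )
    return pd.DataFrame(rows), flagged, n_dropped


def _agreement_reports(
    estimates: pd.DataFrame,
) -> dict[tuple[str, str], AgreementReport]:
    wide = estimates.pivot(index="subject_id", columns="method")
    reports: dict[tuple[str, str], AgreementReport] = {}
    for outcome in OUTCOMES:
        col = _OUTCOME_COLUMNS[outcome]
        for ref in REFERENCES:
            sample = PairedSample(
                predicted=wide[(col, "ARMY1")].to_numpy(),
                reference=wide[(col, ref)].to_numpy(),
                outcome_label=outcome,
            )
            reports[(outcome, ref)] = full_report(sample)
    return reports


def _compliance_summary(
    estimates: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    army = estimates[estimates["method"] == "ARMY1"]
    rows = []
    for sex, service in (("M", config.service_threshold_male),
                         ("F", config.service_threshold_female)):
        sub = army[army["sex"] == sex]
        lo, hi = config.thresholds.band(sex)
        threshold = hi if service is None else service
        statuses = [
            classify_compliance(sex, bf, config.thresholds, threshold)
            for bf in sub["bf_percent"]
        ]
        rows.append({"sex": sex, "threshold_pct": threshold, "n": len(sub),
                     "n_pass": statuses.count("pass"),
                     "n_flag": statuses.count("flag")})
    return pd.DataFrame(rows)


def _reports_frame(reports: dict[tuple[str, str], AgreementReport]) -> pd.DataFrame:
    rows = []
    for (outcome, ref), rep in reports.items():
        d = rep.to_dict()
        d["reference"] = ref
        d["flags"] = ";".join(rep.flags)
        rows.append(d)
    df = pd.DataFrame(rows)
    front = ["outcome_label", "reference", "n"]
    return df[front + [c for c in df.columns if c not in front]]


def _plot_reports(
    estimates: pd.DataFrame,
    reports: dict[tuple[str, str], AgreementReport],
    out_dir: Path,
) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = estimates.pivot(index="subject_id", columns="method")
    units = {"BF%": "%", "FM": "kg", "FFM": "kg"}
    for ref in REFERENCES:
        fig, axes = plt.subplots(3, 2, figsize=(9, 11))
        for i, outcome in enumerate(OUTCOMES):
            col = _OUTCOME_COLUMNS[outcome]
            pred = wide[(col, "ARMY1")].to_numpy()
            refv = wide[(col, ref)].to_numpy()
            rep = reports[(outcome, ref)]
            u = units[outcome]

            ax = axes[i, 0]
            ax.scatter(refv, pred, s=12, alpha=0.7)
            grid = np.linspace(refv.min(), refv.max(), 50)
            ax.plot(grid, grid, "k--", lw=1, label="identity")
            ax.plot(grid, rep.ols_intercept + rep.ols_slope * grid, "r-",
                    lw=1, label="OLS")
            ax.set_xlabel(f"{ref} {outcome} ({u})")
            ax.set_ylabel(f"Equation {outcome} ({u})")
            ax.legend(fontsize=7)

            ax = axes[i, 1]
            means, diffs = (pred + refv) / 2, pred - refv
            ax.scatter(means, diffs, s=12, alpha=0.7)
            for y, style in ((rep.constant_error, "-"),
                             (rep.loa_lower, "--"), (rep.loa_upper, "--")):
                ax.axhline(y, color="r", ls=style, lw=1)
            ax.set_xlabel(f"Mean of methods ({u})")
            ax.set_ylabel(f"Equation - {ref} ({u})")
        fig.tight_layout()
        fig.savefig(out_dir / f"agreement_vs_{ref.lower()}.png", dpi=120)
        plt.close(fig)


def run_study(config: RunConfig) -> StudyResult:
    """Execute one full study run; writes outputs under ``config.out_dir``.

    Files written: ``cohort.csv`` (and ``truth.csv`` in simulate mode),
    ``estimates.csv`` (long: one row per subject x method),
    ``agreement_reports.csv`` / ``.json`` (one row per outcome x
    reference), ``compliance.csv``, ``run.log``, and optional figures.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    try:
        coeffs = (WangCoefficients.from_json(config.wang_json)
                  if config.wang_json else WangCoefficients())

        if config.mode == "simulate":
            cohort_cfg = config.cohort.model_copy(update={"seed": config.seed})
            truth_df, cohort = simulate_cohort(cohort_cfg, coeffs)
            if config.write_truth:
                truth_df.to_csv(out_dir / "truth.csv", index=False)
            if config.equation_json:
                spec = EquationSpec.from_json(config.equation_json)
            else:
                spec = calibrate_one_site_equation(truth_df, cohort)
                logger.info("calibrated one-site equation from simulated cohort")
        else:
            cohort = pd.read_csv(config.input_csv)
            issues = validate_input(config.input_csv)
            for issue in issues:
                logger.log(
                    logging.ERROR if issue["severity"] == "error" else logging.WARNING,
                    "input row %s column %s: %s",
                    issue["row"], issue["column"], issue["message"],
                )
            fatal = [i for i in issues if i["severity"] == "error" and i["row"] is None]
            if fatal:
                raise ValueError(f"input schema invalid: {fatal}")
            bad_rows = {i["row"] for i in issues
                        if i["severity"] == "error" and i["row"] is not None}
            cohort = cohort.drop(index=list(bad_rows))
            if config.equation_json:
                spec = EquationSpec.from_json(config.equation_json)
            else:
                spec = default_equation_spec()
        if not spec.verified:
            logger.warning(
                "equation %r carries UNVERIFIED placeholder coefficients", spec.name
            )
        cohort.to_csv(out_dir / "cohort.csv", index=False)

        n_input = len(cohort)
        estimates, flagged, n_dropped = _estimates_frame(cohort, spec, coeffs)
        if n_input and n_dropped / n_input > 0.20:
            raise RuntimeError(
                f"{n_dropped}/{n_input} subjects dropped (> 20%); aborting"
            )
        logger.info("estimated %d subjects (%d dropped, %d flagged records)",
                    n_input - n_dropped, n_dropped, len(flagged))
        estimates.to_csv(out_dir / "estimates.csv", index=False)

        reports = _agreement_reports(estimates)
        reports_df = _reports_frame(reports)
        reports_df.to_csv(out_dir / "agreement_reports.csv", index=False)
        payload = {
            "n_subjects": n_input - n_dropped,
            "n_dropped": n_dropped,
            "n_flagged_records": len(flagged),
            "flagged": flagged,
            "reports": {f"{o}_vs_{r}": rep.to_dict()
                        for (o, r), rep in reports.items()},
        }
        (out_dir / "agreement_reports.json").write_text(
            json.dumps(payload, indent=2) + "\n", encoding="utf-8"
        )

        compliance = _compliance_summary(estimates, config)
        compliance.to_csv(out_dir / "compliance.csv", index=False)

        if config.plots:
            _plot_reports(estimates, reports, out_dir)

        return StudyResult(
            estimates=estimates,
            reports=reports,
            compliance=compliance,
            n_subjects=n_input - n_dropped,
            n_dropped=n_dropped,
            flagged=flagged,
            out_dir=out_dir,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
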