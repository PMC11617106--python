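"""Circumference-based body-fat equations and compliance classification.

The US Army body composition program estimates body fat percentage (BF%)
from two anthropometric inputs — body mass and a single abdominal
circumference — via sex-specific linear equations of the form

    BF% = b0 + b1 * mass + b2 * circumference

with coefficients published in service regulations.  This module treats
the coefficients as *configuration* (:class:`EquationSpec`) rather than
code constants: the packaged default carries placeholder values marked
UNVERIFIED, and tests use synthetic coefficient sets.  Official values
must be transcribed from the governing regulation (AR 600-9) before any
field use.

Also provided: triplicate-scan averaging, unit conversion between the
metric scanner outputs and the customary imperial equation units,
derivation of fat mass (FM) and fat-free mass (FFM) from BF% and body
mass, and classification against Department of Defense BF% thresholds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "CM_PER_INCH",
    "KG_PER_POUND",
    "ComplianceThresholds",
    "CompositionEstimate",
    "EquationSpec",
    "Sex",
    "average_scan_circumferences",
    "bf_to_composition",
    "classify_compliance",
    "convert_units",
    "default_equation_spec",
    "normalize_sex",
    "one_site_bf_percent",
]

# Exact conversion factors (international yard & pound agreement).
CM_PER_INCH = 2.54
KG_PER_POUND = 0.45359237

Sex = Literal["M", "F"]

_SEX_ALIASES = {
    "m": "M", "male": "M", "M": "M",
    "f": "F", "female": "F", "F": "F",
}


def normalize_sex(sex: str) -> Sex:
    """Map common sex codes ('M', 'male', 'F', 'female', any case) to 'M'/'F'."""
    try:
        return _SEX_ALIASES[str(sex).strip().lower()]  # type: ignore[return-value]
    except KeyError:
        raise ValueError(f"unrecognised sex code: {sex!r} (expected M/F)") from None


class MissingScanWarning(UserWarning):
    """Fewer than the nominal three circumference scans were available."""


@dataclass(frozen=True)
class EquationSpec:
    """Sex-specific linear BF% equation with an explicit unit convention.

    ``mass_unit`` and ``circ_unit`` declare the units the coefficients
    expect; inputs are always supplied in metric (kg, cm) and converted.
    ``rounding_rule`` optionally rounds converted inputs to the nearest
    half unit, mirroring manual field-measurement protocols; the default
    is no rounding (digital anthropometry pipelines are continuous).
    """

    name: str
    intercept_male: float
    coef_mass_male: float
    coef_circ_male: float
    intercept_female: float
    coef_mass_female: float
    coef_circ_female: float
    mass_unit: Literal["kg", "lb"]
    circ_unit: Literal["cm", "in"]
    rounding_rule: Literal["none", "nearest_half_unit"] = "none"
    verified: bool = False

    def __post_init__(self) -> None:
        if self.mass_unit not in ("kg", "lb"):
            raise ValueError(f"mass_unit must be 'kg' or 'lb', got {self.mass_unit!r}")
        if self.circ_unit not in ("cm", "in"):
            raise ValueError(f"circ_unit must be 'cm' or 'in', got {self.circ_unit!r}")
        if self.rounding_rule not in ("none", "nearest_half_unit"):
            raise ValueError(f"unknown rounding_rule {self.rounding_rule!r}")

    def coefficients(self, sex: str) -> tuple[float, float, float]:
        """Return (intercept, mass coefficient, circumference coefficient) for a sex."""
        s = normalize_sex(sex)
        if s == "M":
            coefs = (self.intercept_male, self.coef_mass_male, self.coef_circ_male)
        else:
            coefs = (self.intercept_female, self.coef_mass_female, self.coef_circ_female)
        if any(c is None or (isinstance(c, float) and math.isnan(c)) for c in coefs):
            raise ValueError(f"equation {self.name!r} has no coefficients for sex {s}")
        return coefs

    @classmethod
    def from_json(cls, path: str | Path) -> "EquationSpec":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def default_equation_spec() -> EquationSpec:
    """Load the packaged placeholder equation config.

    The packaged coefficients are UNVERIFIED placeholders (``verified``
    is false); they let the pipeline run end to end but carry no claim of
    matching the official regulation tables.
    """
    ref = resources.files("onesitebf").joinpath("data/army_one_site_unverified.json")
    payload = json.loads(ref.read_text(encoding="utf-8"))
    payload.pop("_comment", None)
    return EquationSpec(**payload)


def average_scan_circumferences(circs: Sequence[float]) -> float:
    """Arithmetic mean of replicate circumference scans (nominally three).

    Fewer than three values still yield a mean but emit a
    :class:`MissingScanWarning`; an empty list or any non-positive value
    is a hard error.
    """
    values = [float(c) for c in circs]
    if not values:
        raise ValueError("no circumference scans provided")
    if any(v <= 0 for v in values):
        raise ValueError(f"non-positive circumference in scans: {values}")
    if len(values) < 3:
        warnings.warn(
            f"only {len(values)} of 3 nominal scans available; mean taken over those",
            MissingScanWarning,
            stacklevel=2,
        )
    return sum(values) / len(values)


def _round_half(x: float) -> float:
    return round(x * 2.0) / 2.0


def convert_units(
    mass_kg: float, circ_cm: float, spec: EquationSpec
) -> tuple[float, float]:
    """Express metric inputs in the units an equation expects.

    Rounding (if the spec requests ``nearest_half_unit``) is applied
    after conversion, matching how field protocols record tape and scale
    readings in the equation's own units.
    """
    if mass_kg <= 0 or circ_cm <= 0:
        raise ValueError("mass and circumference must be positive")
    mass = mass_kg / KG_PER_POUND if spec.mass_unit == "lb" else mass_kg
    circ = circ_cm / CM_PER_INCH if spec.circ_unit == "in" else circ_cm
    if spec.rounding_rule == "nearest_half_unit":
        mass, circ = _round_half(mass), _round_half(circ)
    return mass, circ


def one_site_bf_percent(
    sex: str, mass_kg: float, abdomen_circ_cm: float, spec: EquationSpec
) -> float:
    """Evaluate the sex-specific one-site equation.

    Inputs are metric; they are converted to the spec's declared units
    first.  The raw linear prediction is returned unclipped — values
    outside [0, 100) are the caller's signal of equation misbehaviour
    and must not be masked here.
    """
    intercept, coef_mass, coef_circ = spec.coefficients(sex)
    mass, circ = convert_units(mass_kg, abdomen_circ_cm, spec)
    return intercept + coef_mass * mass + coef_circ * circ


@dataclass(frozen=True)
class CompositionEstimate:
    """BF%, FM and FFM from one method for one subject.

    ``flags`` records quality issues (e.g. out-of-range BF%) without
    altering the numbers; downstream statistics see the raw values.
    """

    subject_id: str
    method: Literal["ARMY1", "DXA", "FOURC"]
    bf_percent: float
    fat_mass_kg: float
    ffm_kg: float
    body_mass_kg: float
    flags: tuple[str, ...] = field(default=())

    @property
    def out_of_range(self) -> bool:
        return not (0.0 <= self.bf_percent < 100.0)


def bf_to_composition(
    subject_id: str,
    method: Literal["ARMY1", "DXA", "FOURC"],
    bf_percent: float,
    body_mass_kg: float,
    extra_flags: Iterable[str] = (),
) -> CompositionEstimate:
    """Derive FM and FFM from BF% and body mass (FM + FFM = mass exactly)."""
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    fm = bf_percent / 100.0 * body_mass_kg
    ffm = body_mass_kg - fm
    flags = list(extra_flags)
    if not (0.0 <= bf_percent < 100.0):
        flags.append("bf_percent_out_of_range")
    return CompositionEstimate(
        subject_id=str(subject_id),
        method=method,
        bf_percent=float(bf_percent),
        fat_mass_kg=fm,
        ffm_kg=ffm,
        body_mass_kg=float(body_mass_kg),
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class ComplianceThresholds:
    """Directive band for service-selectable BF% thresholds, per sex.

    The 2022 DoD physical fitness / body composition directive requires
    service thresholds no lower than 18% (M) / 26% (F) and no higher
    than 26% (M) / 36% (F).
    """

    male_min_pct: float = 18.0
    male_max_pct: float = 26.0
    female_min_pct: float = 26.0
    female_max_pct: float = 36.0

    def __post_init__(self) -> None:
        if self.male_min_pct > self.male_max_pct:
            raise ValueError("male_min_pct exceeds male_max_pct")
        if self.female_min_pct > self.female_max_pct:
            raise ValueError("female_min_pct exceeds female_max_pct")

    def band(self, sex: str) -> tuple[float, float]:
        s = normalize_sex(sex)
        if s == "M":
            return self.male_min_pct, self.male_max_pct
        return self.female_min_pct, self.female_max_pct

    @classmethod
    def from_json(cls, path: str | Path) -> "ComplianceThresholds":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def classify_compliance(
    sex: str,
    bf_percent: float,
    thresholds: ComplianceThresholds | None = None,
    service_threshold_pct: float | None = None,
) -> Literal["pass", "flag"]:
    """Classify a BF% against a service threshold within the directive band.

    A soldier at or below the threshold passes (boundary inclusive); one
    above it is flagged.  The service threshold defaults to the top of
    the sex's directive band and must lie within that band.
    """
    thresholds = thresholds or ComplianceThresholds()
    lo, hi = thresholds.band(sex)
    if service_threshold_pct is None:
        service_threshold_pct = hi
    if not (lo <= service_threshold_pct <= hi):
        raise ValueError(
            f"service threshold {service_threshold_pct}% outside directive band "
            f"[{lo}, {hi}]% for sex {normalize_sex(sex)}"
        )
    return "pass" if bf_percent <= service_threshold_pct else "flag"
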