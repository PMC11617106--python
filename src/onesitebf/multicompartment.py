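"""Criterion body-composition models: 4-compartment and DXA.

The 4-compartment (4C) model partitions body mass into fat, water,
mineral and residual using four independent measurements: body volume BV
(air displacement plethysmography, litres), total body water TBW
(bioimpedance spectroscopy, kg), total body osseous mineral Mo (kg,
derived from DXA bone mineral content) and body mass BM (kg).  Fat mass
is a linear combination

    FM = c_bv*BV + c_tbw*TBW + c_mo*Mo + c_bm*BM

whose default coefficients are the published Wang et al. (2002) values
(2.748, -0.699, 1.129, -2.051).  They are configuration, not constants,
and should be checked against the original source before being trusted.

DXA bone mineral content measures hydroxyapatite-equivalent ash; total
osseous mineral is obtained by dividing BMC by 0.9582.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from onesitebf.equations import CompositionEstimate, bf_to_composition

__all__ = [
    "BMC_TO_MINERAL_DIVISOR",
    "DeviceMeasurements",
    "WangCoefficients",
    "adjust_bmc",
    "dxa_composition",
    "four_c_composition",
    "four_c_fat_mass",
]

# DXA ash (BMC) -> total body osseous mineral Mo.
BMC_TO_MINERAL_DIVISOR = 0.9582


@dataclass(frozen=True)
class WangCoefficients:
    """Multipliers of BV (L), TBW (kg), Mo (kg) and BM (kg) in the 4C FM equation.

    Defaults carry the published Wang et al. (2002) values; verify
    against the original publication before trusting them.
    """

    c_bv: float = 2.748
    c_tbw: float = -0.699
    c_mo: float = 1.129
    c_bm: float = -2.051

    @classmethod
    def from_json(cls, path: str | Path) -> "WangCoefficients":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class DeviceMeasurements:
    """One subject's laboratory device outputs feeding the criterion models."""

    subject_id: str
    body_mass_kg: float
    body_volume_l: float
    tbw_kg: float
    dxa_bmc_kg: float
    dxa_bf_percent: float

    def __post_init__(self) -> None:
        for name in ("body_mass_kg", "body_volume_l", "tbw_kg", "dxa_bmc_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.tbw_kg >= self.body_mass_kg:
            raise ValueError("total body water cannot exceed body mass")
        if self.dxa_bmc_kg >= self.body_mass_kg:
            raise ValueError("bone mineral content cannot exceed body mass")


def adjust_bmc(dxa_bmc_kg: float) -> float:
    """Total body osseous mineral Mo (kg) from DXA bone mineral content.

    Mo = BMC / 0.9582; strictly increasing and scale-equivariant.
    """
    if dxa_bmc_kg <= 0:
        raise ValueError("bone mineral content must be positive")
    return dxa_bmc_kg / BMC_TO_MINERAL_DIVISOR


def four_c_fat_mass(
    meas: DeviceMeasurements, coeffs: WangCoefficients | None = None
) -> float:
    """4C fat mass (kg) from device measurements.

    Mo is derived from the DXA BMC via :func:`adjust_bmc`; the result is
    the raw linear-form value, which may be physiologically implausible
    for inconsistent inputs — flagging happens in
    :func:`four_c_composition`.
    """
    coeffs = coeffs or WangCoefficients()
    mo = adjust_bmc(meas.dxa_bmc_kg)
    return (
        coeffs.c_bv * meas.body_volume_l
        + coeffs.c_tbw * meas.tbw_kg
        + coeffs.c_mo * mo
        + coeffs.c_bm * meas.body_mass_kg
    )


def four_c_composition(
    meas: DeviceMeasurements, coeffs: WangCoefficients | None = None
) -> CompositionEstimate:
    """Full 4C composition estimate (BF%, FM, FFM) for one subject.

    FM outside [0, body mass] is flagged ``fourc_fm_implausible`` and
    propagated unclipped.
    """
    fm = four_c_fat_mass(meas, coeffs)
    bf = 100.0 * fm / meas.body_mass_kg
    flags = []
    if fm < 0 or fm > meas.body_mass_kg:
        flags.append("fourc_fm_implausible")
    return bf_to_composition(
        meas.subject_id, "FOURC", bf, meas.body_mass_kg, extra_flags=flags
    )


def dxa_composition(
    subject_id: str, dxa_bf_percent: float, body_mass_kg: float
) -> CompositionEstimate:
    """DXA composition estimate from the scanner's BF% and the shared body mass."""
    if not (0.0 <= dxa_bf_percent < 100.0):
        raise ValueError(f"DXA BF% out of range: {dxa_bf_percent}")
    return bf_to_composition(subject_id, "DXA", dxa_bf_percent, body_mass_kg)
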