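"""Dose arithmetic: DMSO mass dose and PTZ seizure-threshold dose.

A DMSO solution given at a volume-per-body-weight dose delivers a mass dose

    dose [mg/kg] = concentration [% v/v] / 100
                   x volume [uL/g] x density [mg/uL] x 1000

with the literature DMSO density of 1.1004 mg/uL at 20 C. For tail-vein PTZ
infusion stopped at seizure onset, the threshold dose is the infused drug
mass relative to body weight:

    threshold [mg/kg] = infused volume [mL] x concentration [mg/mL]
                        / (body weight [g] / 1000).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

__all__ = [
    "DMSO_DENSITY_MG_PER_UL",
    "DoseSpec",
    "InfusionSpec",
    "dmso_dose_mg_per_kg",
    "ptz_threshold_mg_per_kg",
    "infused_volume_ml",
    "round_to_printed",
]

#: density of pure DMSO at 20 C, mg per microliter
DMSO_DENSITY_MG_PER_UL = 1.1004


@dataclass(frozen=True)
class DoseSpec:
    """A solvent dose: % v/v concentration, uL/g volume, solvent density."""

    concentration_pct_vv: float
    volume_ul_per_g: float
    density_mg_per_ul: float = DMSO_DENSITY_MG_PER_UL

    def __post_init__(self) -> None:
        if not 0 <= self.concentration_pct_vv <= 100:
            raise ParameterError(
                f"concentration must be in [0, 100] % v/v, got {self.concentration_pct_vv}"
            )
        if self.volume_ul_per_g <= 0:
            raise ParameterError("volume_ul_per_g must be positive")
        if self.density_mg_per_ul <= 0:
            raise ParameterError("density_mg_per_ul must be positive")


@dataclass(frozen=True)
class InfusionSpec:
    """A constant-rate i.v. infusion stopped at a behavioral endpoint."""

    infused_volume_ml: float
    body_weight_g: float
    drug_conc_mg_per_ml: float = 10.0
    infusion_rate_ul_per_min: float = 100.0

    def __post_init__(self) -> None:
        if self.infused_volume_ml < 0:
            raise ParameterError("infused_volume_ml must be non-negative")
        if self.body_weight_g <= 0:
            raise ParameterError("body_weight_g must be positive")
        if self.drug_conc_mg_per_ml <= 0:
            raise ParameterError("drug_conc_mg_per_ml must be positive")
        if self.infusion_rate_ul_per_min <= 0:
            raise ParameterError("infusion_rate_ul_per_min must be positive")


def dmso_dose_mg_per_kg(spec: DoseSpec) -> float:
    """Mass dose (mg/kg) delivered by a % v/v solution at a uL/g volume."""
    return (
        spec.concentration_pct_vv / 100.0
        * spec.volume_ul_per_g
        * spec.density_mg_per_ul
        * 1000.0
    )


def round_to_printed(dose_mg_per_kg: float) -> float:
    """Round a dose the way it is conventionally reported: one decimal
    below 1000 mg/kg, whole numbers above."""
    if dose_mg_per_kg < 1000:
        return round(dose_mg_per_kg, 1)
    return float(round(dose_mg_per_kg))


def ptz_threshold_mg_per_kg(spec: InfusionSpec) -> float:
    """Seizure-threshold dose from infused volume relative to body weight."""
    return spec.infused_volume_ml * spec.drug_conc_mg_per_ml / (
        spec.body_weight_g / 1000.0
    )


def infused_volume_ml(
    duration_s: float, rate_ul_per_min: float = 100.0
) -> float:
    """Volume (mL) delivered by ``duration_s`` of constant-rate infusion."""
    if duration_s < 0:
        raise ParameterError("duration_s must be non-negative")
    if rate_ul_per_min <= 0:
        raise ParameterError("rate_ul_per_min must be positive")
    return duration_s / 60.0 * rate_ul_per_min / 1000.0
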