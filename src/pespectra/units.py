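"""Intensity unit conversions, derived from the constants table at import.

IR intensities all scale linearly with the squared dipole-moment gradient in
normal coordinates, μ_I^Q = Σ_α (∂μ_α/∂Q_I)², whose SI unit is C²·kg⁻¹.  The
commonly reported quantities are

    μ_I^Q                 C²·kg⁻¹  or  D²·Å⁻²·amu⁻¹
    A_I  = N_A μ_I^Q / (12 ε₀ c²)        Napierian integrated molecular
                                          attenuation, m·mol⁻¹ or km·mol⁻¹
    A_I / ln 10                           decadic scale, whose pointwise
                                          lineshape-weighted value ε(ν̃) has
                                          units m²·mol⁻¹ or L·mol⁻¹·cm⁻¹

Raman activities scale with α_I^Q = k_a a_I² + k_b b_I² in C⁴·m²·J⁻²·kg⁻¹,
convertible to m⁴·kg⁻¹ via (1/4πε₀)² and then to Å⁴·amu⁻¹.

Every factor below is computed from CODATA 2018 constants; none is a typed-in
composite literal.
"""

from __future__ import annotations

import math

from .constants import (
    ATOMIC_MASS,
    AVOGADRO,
    COULOMB_CONSTANT,
    DEBYE_TO_CM,
    SPEED_OF_LIGHT,
    VACUUM_PERMITTIVITY,
)

__all__ = ["IR_UNIT_FACTORS", "RAMAN_UNIT_FACTORS", "convert_ir_units",
           "convert_raman_units", "ir_integrated_absorption_coefficient"]

_ANGSTROM = 1e-10  # m

#: multiply N_A/(12 ε0 c²) by μ^Q [C² kg⁻¹] to get A [m mol⁻¹]
MU_Q_TO_NAPIERIAN = AVOGADRO / (12.0 * VACUUM_PERMITTIVITY * SPEED_OF_LIGHT**2)

# value in <unit> = value in SI base of the family × factor
IR_UNIT_FACTORS: dict[str, float] = {
    "C2/kg": 1.0,
    "D2/(A2 amu)": _ANGSTROM**2 * ATOMIC_MASS / DEBYE_TO_CM**2,
    "m/mol": MU_Q_TO_NAPIERIAN,
    "km/mol": MU_Q_TO_NAPIERIAN * 1e-3,
    "m2/mol": MU_Q_TO_NAPIERIAN / math.log(10.0),
    "L/(mol cm)": MU_Q_TO_NAPIERIAN / math.log(10.0) * 10.0,
}

RAMAN_UNIT_FACTORS: dict[str, float] = {
    "C4 m2/(J2 kg)": 1.0,
    "m4/kg": COULOMB_CONSTANT**2,
    "A4/amu": COULOMB_CONSTANT**2 / _ANGSTROM**4 * ATOMIC_MASS,
}

_IR_ALIASES = {
    "c2/kg": "C2/kg", "si": "C2/kg",
    "d2/(a2 amu)": "D2/(A2 amu)", "d2 a-2 amu-1": "D2/(A2 amu)",
    "m/mol": "m/mol", "m mol-1": "m/mol",
    "km/mol": "km/mol", "km mol-1": "km/mol",
    "m2/mol": "m2/mol", "m2 mol-1": "m2/mol",
    "l/(mol cm)": "L/(mol cm)", "l mol-1 cm-1": "L/(mol cm)",
}

_RAMAN_ALIASES = {
    "c4 m2/(j2 kg)": "C4 m2/(J2 kg)", "si": "C4 m2/(J2 kg)",
    "m4/kg": "m4/kg", "m4 kg-1": "m4/kg",
    "a4/amu": "A4/amu", "a4 amu-1": "A4/amu",
}


def _resolve(unit: str, aliases: dict[str, str], table: dict[str, float]) -> str:
    key = aliases.get(unit.strip().lower())
    if key is None:
        raise ValueError(f"unknown unit '{unit}'; known: {sorted(table)}")
    return key


def convert_ir_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an IR intensity between the Table-1-style unit systems."""
    f = IR_UNIT_FACTORS[_resolve(from_unit, _IR_ALIASES, IR_UNIT_FACTORS)]
    t = IR_UNIT_FACTORS[_resolve(to_unit, _IR_ALIASES, IR_UNIT_FACTORS)]
    return value / f * t


def convert_raman_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a Raman activity between the Table-2-style unit systems."""
    f = RAMAN_UNIT_FACTORS[_resolve(from_unit, _RAMAN_ALIASES, RAMAN_UNIT_FACTORS)]
    t = RAMAN_UNIT_FACTORS[_resolve(to_unit, _RAMAN_ALIASES, RAMAN_UNIT_FACTORS)]
    return value / f * t


def ir_integrated_absorption_coefficient(mu_q_si: float) -> float:
    """A_I = N_A μ_I^Q / (12 ε₀ c²) in m·mol⁻¹ from μ_I^Q in C²·kg⁻¹."""
    return MU_Q_TO_NAPIERIAN * mu_q_si
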