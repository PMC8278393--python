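"""Double-harmonic IR and Raman intensities, lineshapes, snapshot averaging.

IR: the molar decadic attenuation coefficient of mode I is

    ε_I(ν̃) = N_A / (12 ln10 ε₀ c²) · μ_I^Q · f(ν̃; ν̃_I, γ_I),

with μ_I^Q = Σ_α (∂μ_α/∂Q_I)² and f a Cauchy (Lorentzian) density whose
half-width at half-maximum is γ_I.  Integrating a band over wavenumber (in
m⁻¹) gives A_I/ln10 with A_I = N_A μ_I^Q/(12 ε₀ c²), the Napierian
integrated molecular attenuation coefficient.

Raman: from the invariants of the polarizability gradient in normal
coordinates — a_I (isotropic mean) and b_I² (anisotropy) — the absolute
differential scattering cross section at temperature T is

    σ′_I = h / (8 ε₀² c ν̃_I) · (ν̃₀ − ν̃_I)⁴ · (k_a a_I² + k_b b_I²)/45
           · [1 − exp(−h c ν̃_I / k T)]⁻¹,

with k_a = 45 and k_b = 7 for light polarized perpendicular to the direction
of observation and propagation (other setups use other coefficients).

Ensemble spectra are plain averages of the per-snapshot broadened spectra on
a common grid.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import cauchy

from .constants import (
    BOLTZMANN,
    CM_TO_PER_METER,
    PLANCK,
    SPEED_OF_LIGHT,
    VACUUM_PERMITTIVITY,
)
from .units import IR_UNIT_FACTORS, MU_Q_TO_NAPIERIAN

__all__ = [
    "RamanSettings",
    "SpectrumGrid",
    "default_grid",
    "ir_mode_strength",
    "ir_epsilon",
    "raman_invariants",
    "raman_cross_section",
    "cauchy_lineshape",
    "ir_spectrum",
    "raman_spectrum",
    "average_spectra",
    "write_spectrum_csv",
    "write_spectrum_json",
    "DEFAULT_HWHM",
]

#: default homogeneous broadening (cm^-1, HWHM)
DEFAULT_HWHM = 3.0

RAMAN_SPECTRUM_UNIT = "C4 s2/(J m2 kg) per cm-1"


def default_grid() -> np.ndarray:
    """0–4000 cm⁻¹ at 0.5 cm⁻¹ spacing."""
    return np.arange(0.0, 4000.0 + 0.25, 0.5)


@dataclass(frozen=True)
class RamanSettings:
    """Incident light and temperature for Raman cross sections."""

    incident_wavenumber: float = 1e7 / 514.5  # cm^-1 (514.5 nm argon line)
    temperature: float = 298.0  # K
    k_a: float = 45.0
    k_b: float = 7.0

    @classmethod
    def from_wavelength_nm(cls, wavelength_nm: float, **kw) -> "RamanSettings":
        return cls(incident_wavenumber=1e7 / wavelength_nm, **kw)

    def __post_init__(self) -> None:
        if self.incident_wavenumber <= 0:
            raise ValueError("incident wavenumber must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class SpectrumGrid:
    """Broadened intensity vs. wavenumber with an explicit unit tag."""

    wavenumbers: np.ndarray  # cm^-1, strictly increasing
    intensities: np.ndarray
    unit: str
    kind: str = ""  # "ir" | "raman"
    snapshots: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.wavenumbers.ndim != 1 or np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if self.intensities.shape != self.wavenumbers.shape:
            raise ValueError("grid and intensity shapes differ")


def cauchy_lineshape(grid: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Normalized Cauchy density per cm⁻¹; f(center ± hwhm) = f(center)/2."""
    if hwhm <= 0:
        raise ValueError(f"HWHM must be positive, got {hwhm}")
    return cauchy.pdf(np.asarray(grid, float), loc=center, scale=hwhm)


def ir_mode_strength(dipole_gradient_normal: np.ndarray) -> np.ndarray:
    """μ_I^Q = Σ_α (∂μ_α/∂Q_I)² per mode, in the squared units of the input."""
    g = np.asarray(dipole_gradient_normal, float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise ValueError(f"expected (n_modes, 3) dipole gradient, got {g.shape}")
    return np.einsum("ia,ia->i", g, g)


def ir_epsilon(
    mu_q_si: float,
    mode_wavenumber: float,
    hwhm: float,
    grid: np.ndarray,
) -> np.ndarray:
    """ε_I(ν̃) in m²·mol⁻¹ on a cm⁻¹ grid, for μ_I^Q in C²·kg⁻¹.

    The lineshape density is converted to a per-m⁻¹ density so that the band
    integral over wavenumber in m⁻¹ equals A_I/ln10 (m·mol⁻¹).
    """
    f_per_m = cauchy_lineshape(grid, mode_wavenumber, hwhm) / CM_TO_PER_METER
    return MU_Q_TO_NAPIERIAN / math.log(10.0) * mu_q_si * f_per_m


def raman_invariants(
    alpha_gradient_normal: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(a_I, b_I²) from per-mode symmetric polarizability gradients (n, 3, 3)."""
    t = np.asarray(alpha_gradient_normal, float)
    if t.ndim == 2:
        t = t[None]
    if t.shape[-2:] != (3, 3):
        raise ValueError(f"expected (n_modes, 3, 3) tensors, got {t.shape}")
    if not np.allclose(t, np.swapaxes(t, -1, -2), atol=1e-10 * max(np.abs(t).max(), 1.0)):
        raise ValueError("polarizability gradients must be symmetric")
    a = np.trace(t, axis1=-2, axis2=-1) / 3.0
    d = np.diagonal(t, axis1=-2, axis2=-1)
    b2 = 0.5 * (
        (d[:, 0] - d[:, 1]) ** 2
        + (d[:, 1] - d[:, 2]) ** 2
        + (d[:, 2] - d[:, 0]) ** 2
    ) + 3.0 * (t[:, 0, 1] ** 2 + t[:, 1, 2] ** 2 + t[:, 2, 0] ** 2)
    return a, b2


def raman_cross_section(
    a: float | np.ndarray,
    b2: float | np.ndarray,
    mode_wavenumber: float | np.ndarray,
    settings: RamanSettings = RamanSettings(),
) -> np.ndarray:
    """σ′_I from SI invariants (a in C²·m·J⁻¹·kg⁻½) and ν̃_I in cm⁻¹."""
    nu_i = np.asarray(mode_wavenumber, float)
    if np.any(nu_i <= 0):
        raise ValueError("mode wavenumbers must be positive")
    if np.any(settings.incident_wavenumber <= nu_i):
        warnings.warn(
            "incident wavenumber below a mode wavenumber: anti-Stokes regime "
            "is not modeled",
            stacklevel=2,
        )
    nu_i_m = nu_i * CM_TO_PER_METER
    nu_0_m = settings.incident_wavenumber * CM_TO_PER_METER
    activity = (settings.k_a * np.asarray(a) ** 2 + settings.k_b * np.asarray(b2)) / 45.0
    prefactor = PLANCK / (8.0 * VACUUM_PERMITTIVITY**2 * SPEED_OF_LIGHT * nu_i_m)
    if settings.temperature == 0.0:
        boltzmann = 1.0
    else:
        boltzmann = 1.0 / (
            1.0
            - np.exp(
                -PLANCK * SPEED_OF_LIGHT * nu_i_m
                / (BOLTZMANN * settings.temperature)
            )
        )
    return prefactor * (nu_0_m - nu_i_m) ** 4 * activity * boltzmann


def ir_spectrum(
    mode_wavenumbers: np.ndarray,
    mu_q_si: np.ndarray,
    hwhm: float = DEFAULT_HWHM,
    grid: np.ndarray | None = None,
    unit: str = "m2/mol",
) -> SpectrumGrid:
    """Sum of broadened ε_I bands; `unit` must be a decadic ε unit."""
    if unit not in ("m2/mol", "L/(mol cm)"):
        raise ValueError("gridded IR spectra are reported in m2/mol or L/(mol cm)")
    grid = default_grid() if grid is None else np.asarray(grid, float)
    total = np.zeros_like(grid)
    for nu, mq in zip(np.asarray(mode_wavenumbers, float), np.asarray(mu_q_si, float)):
        total += ir_epsilon(mq, nu, hwhm, grid)
    total *= IR_UNIT_FACTORS[unit] / IR_UNIT_FACTORS["m2/mol"]
    return SpectrumGrid(wavenumbers=grid, intensities=total, unit=unit, kind="ir")


def raman_spectrum(
    mode_wavenumbers: np.ndarray,
    a: np.ndarray,
    b2: np.ndarray,
    settings: RamanSettings = RamanSettings(),
    hwhm: float = DEFAULT_HWHM,
    grid: np.ndarray | None = None,
) -> SpectrumGrid:
    """Sum of broadened σ′_I bands (cross section × per-cm⁻¹ density)."""
    grid = default_grid() if grid is None else np.asarray(grid, float)
    sigma = raman_cross_section(a, b2, mode_wavenumbers, settings)
    total = np.zeros_like(grid)
    for nu, s in zip(np.atleast_1d(np.asarray(mode_wavenumbers, float)),
                     np.atleast_1d(sigma)):
        total += s * cauchy_lineshape(grid, nu, hwhm)
    return SpectrumGrid(
        wavenumbers=grid, intensities=total, unit=RAMAN_SPECTRUM_UNIT, kind="raman"
    )


def average_spectra(per_snapshot: list[SpectrumGrid]) -> SpectrumGrid:
    """Pointwise mean over snapshots; grids and units must coincide."""
    if not per_snapshot:
        raise ValueError("no spectra to average")
    first = per_snapshot[0]
    for s in per_snapshot[1:]:
        if s.unit != first.unit or s.kind != first.kind:
            raise ValueError("cannot average spectra with different units/kinds")
        if not np.array_equal(s.wavenumbers, first.wavenumbers):
            raise ValueError("cannot average spectra on different grids")
    mean = np.mean([s.intensities for s in per_snapshot], axis=0)
    ids = [i for s in per_snapshot for i in (s.snapshots or [])]
    return SpectrumGrid(
        wavenumbers=first.wavenumbers.copy(),
        intensities=mean,
        unit=first.unit,
        kind=first.kind,
        snapshots=ids,
    )


def write_spectrum_csv(spectrum: SpectrumGrid, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"wavenumber_cm-1", f"intensity [{spectrum.unit}]"])
        for nu, y in zip(spectrum.wavenumbers, spectrum.intensities):
            writer.writerow([f"{nu:.4f}", f"{y:.10e}"])


def write_spectrum_json(spectrum: SpectrumGrid, path: str | Path) -> None:
    payload = {
        "kind": spectrum.kind,
        "unit": spectrum.unit,
        "snapshots": spectrum.snapshots,
        "wavenumbers_cm-1": spectrum.wavenumbers.tolist(),
        "intensities": spectrum.intensities.tolist(),
    }
    Path(path).write_text(json.dumps(payload))
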