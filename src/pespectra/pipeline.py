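"""End-to-end desk-scale workflow: embedded core → PHVA modes → IR/Raman.

The pipeline assembles the core Hessian as (intramolecular toy potential) +
(analytic embedding Hessian E_es + E_ind + E_LJ), performs the partial-
Hessian vibrational analysis, transforms the toy dipole / bond-polarizability
gradients to normal coordinates, and broadens and averages spectra over
snapshot ensembles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import ATOMIC_MASS, AU_POLARIZABILITY_TO_SI, BOHR_RADIUS, \
    ELEMENTARY_CHARGE
from .energy import EnergyReport, total_report
from .fixtures import (
    DEFAULT_CORE_PARTIAL_CHARGES,
    BondPolarizabilityParams,
    SpringModel,
    core_spring_model,
    toy_dipole_surface,
    toy_polarizability_surface,
)
from .spectra import (
    DEFAULT_HWHM,
    RamanSettings,
    SpectrumGrid,
    average_spectra,
    ir_mode_strength,
    ir_spectrum,
    raman_invariants,
    raman_spectrum,
)
from .system import CoreAtom, EnvironmentSite
from .vibrations import (
    PHVA_CUTOFF_WAVENUMBER,
    NormalModeSet,
    drop_null_modes,
    filter_modes,
    mass_weight_hessian,
    normal_modes,
    project_translations_rotations,
)

__all__ = ["SnapshotResult", "analyze_snapshot", "ensemble_spectra"]

#: a.u. dipole gradient in normal coordinates (e · amu^-1/2) → C·kg^-1/2
DIPOLE_GRAD_Q_TO_SI = ELEMENTARY_CHARGE / math.sqrt(ATOMIC_MASS)
#: a.u. polarizability gradient in normal coordinates → C²·m·J⁻¹·kg^-1/2
POL_GRAD_Q_TO_SI = AU_POLARIZABILITY_TO_SI / BOHR_RADIUS / math.sqrt(ATOMIC_MASS)


@dataclass
class SnapshotResult:
    """Everything the spectral pipeline derives from one snapshot."""

    modes: NormalModeSet
    energy: EnergyReport
    mu_q_si: np.ndarray  # (n_modes,) C^2 kg^-1
    raman_a_si: np.ndarray  # (n_modes,)
    raman_b2_si: np.ndarray  # (n_modes,)
    ir: SpectrumGrid
    raman: SpectrumGrid


def analyze_snapshot(
    core: list[CoreAtom],
    sites: list[EnvironmentSite],
    spring: SpringModel | None = None,
    partial_charges: np.ndarray | None = None,
    bond_params: BondPolarizabilityParams = BondPolarizabilityParams(),
    project: bool = False,
    cutoff_wavenumber: float = PHVA_CUTOFF_WAVENUMBER,
    hwhm: float = DEFAULT_HWHM,
    raman_settings: RamanSettings = RamanSettings(),
    grid: np.ndarray | None = None,
    induction_tol: float = 1e-10,
) -> SnapshotResult:
    positions = np.array([a.position for a in core])
    masses = np.array([a.mass for a in core])
    if spring is None:
        spring = core_spring_model(core)
    report = total_report(sites, core, derivatives=2, induction_tol=induction_tol)
    hessian = spring.hessian(positions) + report.hessian
    h_mw = mass_weight_hessian(hessian, masses)
    if project:
        h_mw = project_translations_rotations(h_mw, positions, masses)
    modes = normal_modes(h_mw, masses, positions, projected=project)
    if project:
        modes = drop_null_modes(modes)
    modes = filter_modes(modes, cutoff_wavenumber)
    if np.any(modes.wavenumbers <= 0.0):
        # zero/imaginary modes carry no harmonic band; drop them before the
        # intensity formulas (which require ν̃ > 0)
        keep = modes.wavenumbers > 0.0
        modes = replace(modes, wavenumbers=modes.wavenumbers[keep],
                        modes=modes.modes[:, keep])

    if partial_charges is None and len(core) == DEFAULT_CORE_PARTIAL_CHARGES.size:
        partial_charges = DEFAULT_CORE_PARTIAL_CHARGES
    _, dmu = toy_dipole_surface(core, sites or None, charges=partial_charges)
    disp = modes.cartesian_displacements()  # (3N, n_modes)
    dmu_q = disp.T @ dmu * DIPOLE_GRAD_Q_TO_SI  # (n_modes, 3)
    mu_q = ir_mode_strength(dmu_q)

    _, dalpha = toy_polarizability_surface(core, bond_params)
    dalpha_q = np.einsum("im,iab->mab", disp, dalpha) * POL_GRAD_Q_TO_SI
    a, b2 = raman_invariants(dalpha_q)

    ir = ir_spectrum(modes.wavenumbers, mu_q, hwhm=hwhm, grid=grid)
    raman = raman_spectrum(
        modes.wavenumbers, a, b2, settings=raman_settings, hwhm=hwhm, grid=grid
    )
    return SnapshotResult(
        modes=modes, energy=report, mu_q_si=mu_q,
        raman_a_si=a, raman_b2_si=b2, ir=ir, raman=raman,
    )


def ensemble_spectra(
    snapshots: list[tuple[list[CoreAtom], list[EnvironmentSite]]],
    kind: str = "ir",
    **kwargs,
) -> tuple[SpectrumGrid, list[SnapshotResult]]:
    """Per-snapshot analysis + pointwise averaging (the N-snapshot mean)."""
    if kind not in ("ir", "raman"):
        raise ValueError("kind must be 'ir' or 'raman'")
    results = []
    for j, (core, sites) in enumerate(snapshots):
        res = analyze_snapshot(core, sites, **kwargs)
        res.ir.snapshots = [j]
        res.raman.snapshots = [j]
        results.append(res)
    mean = average_spectra([getattr(r, kind) for r in results])
    return mean, results
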