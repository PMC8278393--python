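"""Partial-Hessian vibrational analysis (PHVA).

The Hessian handled here is the core–core block only: the environment is
frozen, so no environment masses ever enter.  Mass-weighting uses per-
coordinate atomic masses, H'_ij = H_ij / √(m_i m_j); an eigenanalysis of H'
gives normal modes, whose eigenvalues λ (hartree·bohr⁻²·amu⁻¹) convert to
wavenumbers through a single constant chain,

    ν̃ = sign(λ) · √|λ| · √(E_h / (a₀² u)) / (2πc),

reported in cm⁻¹ with imaginary frequencies encoded as negative values.

For a free molecule at a stationary point, six eigenvalues (five for linear
molecules) correspond to overall translation and rotation.  Under PHVA the
embedded core is not free and those motions mix into genuine low-frequency
modes, so projection is optional here: either project the
translational/rotational subspace out of the mass-weighted Hessian before
diagonalizing, or keep all modes and drop the contaminated low-frequency ones
with a wavenumber cutoff (the 750 cm⁻¹ preset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .constants import WAVENUMBER_FROM_EIGVAL

__all__ = [
    "NormalModeSet",
    "mass_weight_hessian",
    "normal_modes",
    "project_translations_rotations",
    "filter_modes",
    "gradient_to_normal_coordinates",
    "PHVA_CUTOFF_WAVENUMBER",
]

#: wavenumber cutoff below which PHVA modes are considered contaminated by
#: global translation/rotation of the embedded core (cm^-1)
PHVA_CUTOFF_WAVENUMBER = 750.0

LINEAR_MOI_RATIO = 1e-8


@dataclass(frozen=True)
class NormalModeSet:
    """Normal modes of a (partial) Hessian.

    ``modes`` has orthonormal columns in mass-weighted coordinates; Cartesian
    displacements of mode I are modes[:, I] / sqrt(masses per coordinate).
    """

    wavenumbers: np.ndarray  # (n_modes,) cm^-1, negative = imaginary
    modes: np.ndarray  # (3N, n_modes)
    masses: np.ndarray  # (N,) amu
    geometry: np.ndarray  # (N, 3) bohr
    projected: bool = False
    phva: bool = True

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def cartesian_displacements(self) -> np.ndarray:
        """Columns ∂x_i/∂Q_I = L_iI / √m_i (bohr · amu^-1/2 per unit Q)."""
        m3 = np.repeat(self.masses, 3)
        return self.modes / np.sqrt(m3)[:, None]


def mass_weight_hessian(hessian: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """H'_ij = H_ij / sqrt(m_i m_j) with per-coordinate masses (amu)."""
    hessian = np.asarray(hessian, float)
    masses = np.asarray(masses, float)
    m3 = np.repeat(masses, 3)
    if hessian.shape != (m3.size, m3.size):
        raise ValueError(
            f"Hessian shape {hessian.shape} inconsistent with {masses.size} atoms"
        )
    inv_sqrt = 1.0 / np.sqrt(m3)
    return hessian * np.outer(inv_sqrt, inv_sqrt)


def eigenvalue_to_wavenumber(eigval: np.ndarray) -> np.ndarray:
    """hartree·bohr⁻²·amu⁻¹ eigenvalues → signed wavenumbers in cm⁻¹."""
    eigval = np.asarray(eigval, float)
    return np.sign(eigval) * np.sqrt(np.abs(eigval)) * WAVENUMBER_FROM_EIGVAL


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    out = vecs.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def normal_modes(
    hessian_mw: np.ndarray,
    masses: np.ndarray,
    geometry: np.ndarray,
    projected: bool = False,
) -> NormalModeSet:
    """Eigenanalysis of a mass-weighted Hessian.

    Wavenumbers are sorted ascending; eigenvector signs are fixed by making
    the largest-magnitude component positive, so the decomposition is
    reproducible.
    """
    hessian_mw = np.asarray(hessian_mw, float)
    scale = max(np.abs(hessian_mw).max(), 1.0)
    if np.abs(hessian_mw - hessian_mw.T).max() > 1e-9 * scale:
        raise ValueError("mass-weighted Hessian must be symmetric")
    vals, vecs = scipy.linalg.eigh(hessian_mw)
    nu = eigenvalue_to_wavenumber(vals)
    order = np.argsort(nu, kind="stable")
    return NormalModeSet(
        wavenumbers=nu[order],
        modes=_fix_eigenvector_signs(vecs[:, order]),
        masses=np.asarray(masses, float),
        geometry=np.asarray(geometry, float).reshape(-1, 3),
        projected=projected,
    )


def _is_linear(geometry: np.ndarray, masses: np.ndarray) -> bool:
    com = masses @ geometry / masses.sum()
    d = geometry - com
    inertia = np.einsum("n,nij->ij", masses,
                        np.einsum("ni,nj->nij", d, d))
    inertia = np.trace(inertia) * np.eye(3) - inertia
    moments = np.sort(np.abs(np.linalg.eigvalsh(inertia)))
    return moments[0] < LINEAR_MOI_RATIO * max(moments[-1], 1e-300)


def translation_rotation_basis(
    geometry: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors, shape (3N, 6|5)."""
    geometry = np.asarray(geometry, float).reshape(-1, 3)
    masses = np.asarray(masses, float)
    n = masses.size
    sqrt_m = np.sqrt(masses)
    com = masses @ geometry / masses.sum()
    d = geometry - com
    vecs = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = sqrt_m
        vecs.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        v = np.cross(d, e[None, :]) * sqrt_m[:, None]
        vecs.append(v.ravel())
    basis = np.column_stack(vecs)
    # Gram-Schmidt via QR; drop numerically null rotations (linear molecules,
    # single atoms)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1e-300)
    return q[:, keep]


def project_translations_rotations(
    hessian_mw: np.ndarray, geometry: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """P H P with P projecting out mass-weighted translations/rotations."""
    basis = translation_rotation_basis(geometry, masses)
    P = np.eye(hessian_mw.shape[0]) - basis @ basis.T
    return P @ np.asarray(hessian_mw, float) @ P


def drop_null_modes(modes: NormalModeSet, tol_wavenumber: float = 1e-2) -> NormalModeSet:
    """Remove the near-zero modes a projected Hessian produces."""
    n_tr = translation_rotation_basis(modes.geometry, modes.masses).shape[1]
    null = np.argsort(np.abs(modes.wavenumbers))[:n_tr]
    keep = np.setdiff1d(np.arange(modes.n_modes), null)
    return replace(
        modes,
        wavenumbers=modes.wavenumbers[keep],
        modes=modes.modes[:, keep],
    )


def filter_modes(
    modes: NormalModeSet, cutoff_wavenumber: float = PHVA_CUTOFF_WAVENUMBER
) -> NormalModeSet:
    """Retain modes with ν̃ ≥ cutoff (the PHVA decontamination filter)."""
    keep = modes.wavenumbers >= cutoff_wavenumber
    if not keep.any():
        warnings.warn(
            f"cutoff {cutoff_wavenumber} cm^-1 removes every mode", stacklevel=2
        )
    return replace(
        modes,
        wavenumbers=modes.wavenumbers[keep],
        modes=modes.modes[:, keep],
    )


def gradient_to_normal_coordinates(
    cartesian_gradient: np.ndarray, modes: NormalModeSet
) -> np.ndarray:
    """Transform a property gradient from Cartesian to normal coordinates.

    ∂X/∂Q_I = Σ_i (∂X/∂x_i) L_iI / √m_i.  Input shape (3N, P) → output
    (n_modes, P); units gain amu^-1/2 relative to the input.
    """
    g = np.asarray(cartesian_gradient, float)
    if g.ndim == 1:
        g = g[:, None]
    return modes.cartesian_displacements().T @ g
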