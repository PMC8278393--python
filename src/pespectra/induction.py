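"""Environment polarization: induced dipoles, induction energy, derivatives.

Polarizable sites carry dipole–dipole polarizabilities α_s.  The induced
dipoles minimize the classical polarization functional

    U(μ) = ½ Σ_s μ_s·α_s⁻¹·μ_s − ½ Σ_{s≠t} μ_s·T2(R_s,R_t)·μ_t − Σ_s μ_s·F_s

whose stationarity condition is the linear system A μ = F with

    A: diagonal 3×3 blocks α_s⁻¹, off-diagonal blocks −T2(R_s,R_t)
       (zero for same-fragment / excluded pairs),
    F: the permanent field at each site (core nuclei + foreign-fragment
       multipoles; a site never feels its own fragment).

At the solution the induction energy is E_ind = −½ μ·F ≤ 0.  The energy is
variational in μ, so first geometric derivatives need no response of μ:
∂E_ind/∂g = −μ·∂F/∂g, and second derivatives add one linear solve per core
coordinate:

    ∂²E_ind/∂g₁∂g₂ = −(∂F/∂g₁)·A⁻¹·(∂F/∂g₂) − μ·∂²F/∂g₁∂g₂.

Only the nuclear part of F depends on core coordinates; the permanent
multipole potentials do not move with the core.

The linear system is solved with a preconditioned conjugate-gradient
iteration (block-Jacobi preconditioner built from the site polarizabilities,
iteration cap 10 000); dense solves back it as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .multiindex import UNIT, MultiIndex, indices_of_order, tensor_table
from .system import CoreAtom, EnvironmentSite, excluded

__all__ = [
    "ResponseMatrix",
    "FieldVector",
    "InducedMoments",
    "ConditioningError",
    "SolverError",
    "assemble_response_matrix",
    "total_site_field",
    "solve_induced_moments",
    "induction_energy",
    "nuclear_potential_derivatives",
    "induction_gradient",
    "induction_hessian",
    "induction_report",
]


class ConditioningError(ValueError):
    """Response matrix is not positive definite."""


class SolverError(RuntimeError):
    """Iterative induced-dipole solver failed to converge."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class ResponseMatrix:
    """Dense classical linear-response matrix over polarizable sites."""

    matrix: np.ndarray  # (3S, 3S)
    site_indices: list[int]  # global index of each polarizable site

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)


@dataclass
class FieldVector:
    """Stacked permanent fields at polarizable sites, by provenance."""

    nuclear: np.ndarray  # (3S,)
    multipole: np.ndarray  # (3S,)

    @property
    def total(self) -> np.ndarray:
        return self.nuclear + self.multipole


@dataclass
class InducedMoments:
    """Induced dipoles per polarizable site (e·bohr), stacked."""

    moments: np.ndarray  # (3S,)
    residual: float
    iterations: int


def _dd_block(r_s: np.ndarray, r_t: np.ndarray) -> np.ndarray:
    t = tensor_table(r_s, r_t, 2)
    return np.array(
        [
            [t[(2, 0, 0)], t[(1, 1, 0)], t[(1, 0, 1)]],
            [t[(1, 1, 0)], t[(0, 2, 0)], t[(0, 1, 1)]],
            [t[(1, 0, 1)], t[(0, 1, 1)], t[(0, 0, 2)]],
        ]
    )


def polarizable_indices(sites: list[EnvironmentSite]) -> list[int]:
    return [i for i, s in enumerate(sites) if s.is_polarizable]


def assemble_response_matrix(sites: list[EnvironmentSite]) -> ResponseMatrix:
    idx = polarizable_indices(sites)
    n = len(idx)
    A = np.zeros((3 * n, 3 * n))
    for a, si in enumerate(idx):
        pol = sites[si].polarizability
        try:
            inv = np.linalg.inv(pol)
        except np.linalg.LinAlgError as exc:
            raise ConditioningError(
                f"site {si} ({sites[si].element}) has a singular polarizability"
            ) from exc
        A[3 * a : 3 * a + 3, 3 * a : 3 * a + 3] = inv
        for b in range(a + 1, n):
            sj = idx[b]
            if excluded(si, sj, sites):
                continue
            blk = -_dd_block(sites[si].position, sites[sj].position)
            A[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] = blk
            A[3 * b : 3 * b + 3, 3 * a : 3 * a + 3] = blk.T
    try:
        np.linalg.cholesky(A) if n else None
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            "response matrix is not positive definite; sites too close or "
            "polarizabilities too large"
        ) from exc
    return ResponseMatrix(matrix=A, site_indices=idx)


def total_site_field(
    sites: list[EnvironmentSite], core: list[CoreAtom]
) -> FieldVector:
    """Permanent field at each polarizable site: nuclei + foreign multipoles."""
    idx = polarizable_indices(sites)
    n = len(idx)
    f_nuc = np.zeros(3 * n)
    f_mul = np.zeros(3 * n)
    for a, si in enumerate(idx):
        r_s = sites[si].position
        # field from core nuclei: F_i = -V^nuc[e_i]
        for atom in core:
            table = tensor_table(atom.position, r_s, 1)
            for i in range(3):
                f_nuc[3 * a + i] -= atom.charge * table[UNIT[i].as_tuple()]
        # field from permanent multipoles on foreign, non-excluded sites
        for sj, other in enumerate(sites):
            if excluded(si, sj, sites):
                continue
            table = None
            for order, comps in other.multipoles.items():
                sign = -1.0 if order % 2 else 1.0
                if table is None:
                    table = tensor_table(
                        other.position, r_s, other.max_order + 1
                    )
                for beta, m in zip(indices_of_order(order), comps):
                    if m == 0.0:
                        continue
                    w = sign * m / beta.factorial()
                    for i in range(3):
                        f_mul[3 * a + i] -= w * table[(beta + UNIT[i]).as_tuple()]
    return FieldVector(nuclear=f_nuc, multipole=f_mul)


def solve_induced_moments(
    response: ResponseMatrix,
    field: FieldVector | np.ndarray,
    tol: float = 1e-10,
    max_iterations: int = 10_000,
) -> InducedMoments:
    """PCG solve of A μ = F with a block-Jacobi (site polarizability) preconditioner."""
    b = field.total if isinstance(field, FieldVector) else np.asarray(field, float)
    A = response.matrix
    n = A.shape[0]
    if n == 0 or not np.any(b):
        return InducedMoments(moments=np.zeros(n), residual=0.0, iterations=0)
    blocks = [
        np.linalg.inv(A[3 * a : 3 * a + 3, 3 * a : 3 * a + 3])
        for a in range(n // 3)
    ]

    def precond(x: np.ndarray) -> np.ndarray:
        y = np.empty_like(x)
        for a, blk in enumerate(blocks):
            y[3 * a : 3 * a + 3] = blk @ x[3 * a : 3 * a + 3]
        return y

    residuals: list[float] = []
    bnorm = np.linalg.norm(b)

    def callback(xk: np.ndarray) -> None:
        residuals.append(float(np.linalg.norm(A @ xk - b) / bnorm))

    M = LinearOperator((n, n), matvec=precond)
    mu, info = cg(A, b, rtol=tol * 1e-2, atol=0.0, maxiter=max_iterations,
                  M=M, callback=callback)
    res = float(np.linalg.norm(A @ mu - b) / bnorm)
    if info != 0 or res > tol:
        raise SolverError(
            f"induced-dipole solver did not reach {tol:g} "
            f"(residual {res:.3e} after {len(residuals)} iterations)",
            residuals,
        )
    return InducedMoments(moments=mu, residual=res, iterations=len(residuals))


def induction_energy(moments: InducedMoments | np.ndarray,
                     field: FieldVector | np.ndarray) -> float:
    """E_ind = −½ μ·F at the variational solution."""
    mu = moments.moments if isinstance(moments, InducedMoments) else np.asarray(moments)
    f = field.total if isinstance(field, FieldVector) else np.asarray(field)
    return float(-0.5 * mu @ f)


def nuclear_potential_derivatives(
    core: list[CoreAtom],
    site_position: np.ndarray,
    alpha: MultiIndex,
    d_order: int,
) -> np.ndarray:
    """Geometric derivatives of V^nuc[α](R_s) with respect to core coordinates.

    Returns shape (3N,) for d_order=1 or (3N, 3N) for d_order=2; the second
    derivative is block-diagonal over atoms (each potential term involves a
    single nucleus).  Derivatives of the multipole potentials are exactly
    zero, as those do not depend on core positions.
    """
    if d_order not in (1, 2):
        raise ValueError("d_order must be 1 or 2")
    n3 = 3 * len(core)
    if d_order == 1:
        out = np.zeros(n3)
        for n, atom in enumerate(core):
            table = tensor_table(atom.position, site_position, alpha.order + 1)
            for g in range(3):
                out[3 * n + g] = -atom.charge * table[(alpha + UNIT[g]).as_tuple()]
        return out
    out2 = np.zeros((n3, n3))
    for n, atom in enumerate(core):
        table = tensor_table(atom.position, site_position, alpha.order + 2)
        for g1 in range(3):
            for g2 in range(3):
                out2[3 * n + g1, 3 * n + g2] = atom.charge * table[
                    (alpha + UNIT[g1] + UNIT[g2]).as_tuple()
                ]
    return out2


def _field_first_derivative(
    response: ResponseMatrix, sites: list[EnvironmentSite], core: list[CoreAtom]
) -> np.ndarray:
    """∂F_{s,i}/∂R_{n,g}: shape (3S, 3N).  Only the nuclear field moves."""
    n3 = 3 * len(core)
    s3 = 3 * response.n_sites
    dF = np.zeros((s3, n3))
    for a, si in enumerate(response.site_indices):
        r_s = sites[si].position
        for n, atom in enumerate(core):
            table = tensor_table(atom.position, r_s, 2)
            for i in range(3):
                for g in range(3):
                    dF[3 * a + i, 3 * n + g] = atom.charge * table[
                        (UNIT[i] + UNIT[g]).as_tuple()
                    ]
    return dF


def _field_second_derivative_contraction(
    mu: np.ndarray,
    response: ResponseMatrix,
    sites: list[EnvironmentSite],
    core: list[CoreAtom],
) -> np.ndarray:
    """Σ_{s,i} μ_{s,i} ∂²F_{s,i}/∂g₁∂g₂: (3N, 3N), block-diagonal over atoms."""
    n3 = 3 * len(core)
    out = np.zeros((n3, n3))
    for a, si in enumerate(response.site_indices):
        r_s = sites[si].position
        for n, atom in enumerate(core):
            table = tensor_table(atom.position, r_s, 3)
            for i in range(3):
                m = mu[3 * a + i]
                if m == 0.0:
                    continue
                for g1 in range(3):
                    for g2 in range(g1, 3):
                        v = -m * atom.charge * table[
                            (UNIT[i] + UNIT[g1] + UNIT[g2]).as_tuple()
                        ]
                        out[3 * n + g1, 3 * n + g2] += v
                        if g2 != g1:
                            out[3 * n + g2, 3 * n + g1] += v
    return out


@dataclass
class InductionReport:
    energy: float
    gradient: np.ndarray
    hessian: np.ndarray
    moments: InducedMoments
    field: FieldVector


def induction_report(
    sites: list[EnvironmentSite],
    core: list[CoreAtom],
    tol: float = 1e-10,
    derivatives: int = 2,
) -> InductionReport:
    response = assemble_response_matrix(sites)
    field = total_site_field(sites, core)
    n3 = 3 * len(core)
    if response.n_sites == 0:
        zero = InducedMoments(np.zeros(0), 0.0, 0)
        return InductionReport(0.0, np.zeros(n3), np.zeros((n3, n3)), zero, field)
    mu = solve_induced_moments(response, field, tol=tol)
    energy = induction_energy(mu, field)
    grad = np.zeros(n3)
    hess = np.zeros((n3, n3))
    if derivatives >= 1:
        dF = _field_first_derivative(response, sites, core)
        grad = -mu.moments @ dF
        if derivatives >= 2:
            # one dense solve with 3N right-hand sides against A
            X = np.linalg.solve(response.matrix, dF)
            hess = -dF.T @ X - _field_second_derivative_contraction(
                mu.moments, response, sites, core
            )
            hess = 0.5 * (hess + hess.T)
    return InductionReport(energy, grad, hess, mu, field)


def induction_gradient(
    sites: list[EnvironmentSite], core: list[CoreAtom], tol: float = 1e-10
) -> np.ndarray:
    return induction_report(sites, core, tol=tol, derivatives=1).gradient


def induction_hessian(
    sites: list[EnvironmentSite], core: list[CoreAtom], tol: float = 1e-10
) -> np.ndarray:
    return induction_report(sites, core, tol=tol, derivatives=2).hessian
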