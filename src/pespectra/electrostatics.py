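"""Permanent-multipole ↔ core-charge electrostatics with analytic derivatives.

The classical electrostatic energy between the environment's permanent
multipoles and the core nuclei is

    E_es = Σ_s Σ_{|α| ≤ K_s} (−1)^|α|/α! · M_s^[α] · Σ_n Z_n T^[α](R_s, R_n)

with raw Cartesian moments M^[α] and the interaction-tensor convention of
:mod:`pespectra.multiindex`.  The sign factor (−1)^|α| makes the |α| = 0 term
the bare Coulomb charge–charge energy and reproduces the two-point-charge
limit of a physical dipole; both limits are enforced by tests against
explicit point-charge arrays.

Geometric derivatives with respect to core coordinates simply raise the
tensor order: ∂/∂R_{n,g} T^[α](R_s, R_n) = T^[α+e_g](R_s, R_n).  Because each
energy term involves a single nucleus, the electrostatic Hessian is exactly
block-diagonal over core atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .multiindex import UNIT, indices_of_order, tensor_table
from .system import CoreAtom, EnvironmentSite

__all__ = ["EsReport", "electrostatic_energy", "electrostatic_gradient",
           "electrostatic_hessian", "electrostatic_report"]


@dataclass
class EsReport:
    """Electrostatic energy with derivatives and per-order decomposition."""

    energy: float
    gradient: np.ndarray  # (3N,)
    hessian: np.ndarray  # (3N, 3N)
    per_order: dict[int, float] = field(default_factory=dict)


def _site_terms(site: EnvironmentSite):
    """Yield (order, multi-index, prefactor × component) for one site."""
    for order, comps in site.multipoles.items():
        sign = -1.0 if order % 2 else 1.0
        for alpha, m in zip(indices_of_order(order), comps):
            if m != 0.0:
                yield order, alpha, sign * m / alpha.factorial()


def electrostatic_report(
    sites: list[EnvironmentSite], core: list[CoreAtom], derivatives: int = 2
) -> EsReport:
    """Energy and (optionally) gradient/Hessian in one pass over site–atom pairs."""
    n3 = 3 * len(core)
    energy = 0.0
    per_order: dict[int, float] = {}
    grad = np.zeros(n3)
    hess = np.zeros((n3, n3))
    for site in sites:
        k_s = site.max_order
        if k_s < 0:
            continue
        terms = list(_site_terms(site))
        for n, atom in enumerate(core):
            table = tensor_table(site.position, atom.position, k_s + derivatives)
            for order, alpha, coeff in terms:
                w = coeff * atom.charge
                energy_term = w * table[alpha.as_tuple()]
                energy += energy_term
                per_order[order] = per_order.get(order, 0.0) + energy_term
                if derivatives >= 1:
                    for g in range(3):
                        grad[3 * n + g] += w * table[(alpha + UNIT[g]).as_tuple()]
                if derivatives >= 2:
                    for g1 in range(3):
                        for g2 in range(g1, 3):
                            v = w * table[(alpha + UNIT[g1] + UNIT[g2]).as_tuple()]
                            hess[3 * n + g1, 3 * n + g2] += v
                            if g2 != g1:
                                hess[3 * n + g2, 3 * n + g1] += v
    return EsReport(energy=energy, gradient=grad, hessian=hess, per_order=per_order)


def electrostatic_energy(sites: list[EnvironmentSite], core: list[CoreAtom]) -> float:
    return electrostatic_report(sites, core, derivatives=0).energy


def electrostatic_gradient(
    sites: list[EnvironmentSite], core: list[CoreAtom]
) -> np.ndarray:
    return electrostatic_report(sites, core, derivatives=1).gradient


def electrostatic_hessian(
    sites: list[EnvironmentSite], core: list[CoreAtom]
) -> np.ndarray:
    return electrostatic_report(sites, core, derivatives=2).hessian
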