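"""6-12 Lennard-Jones interaction between core and environment atoms.

    E_LJ = Σ_{n,s} 4 ε_sn [ (σ_sn/r_ns)^12 − (σ_sn/r_ns)^6 ]

with Lorentz–Berthelot combination σ_sn = ½(σ_s + σ_n), ε_sn = √(ε_s ε_n).
Environment sites without LJ parameters contribute nothing (a single warning
is emitted).  There is no cutoff or switching; truncation of the environment
is a separate, geometric concern.

Because the energy is a sum of core–environment pair terms, the Hessian with
respect to core coordinates is block-diagonal over core atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .system import CoreAtom, EnvironmentSite

__all__ = ["LJPairTable", "lj_energy", "lj_gradient", "lj_hessian", "lj_report"]

MIN_PAIR_DISTANCE = 1e-6  # bohr


@dataclass(frozen=True)
class LJPairTable:
    """Combined pair parameters: sigma[n, s] (bohr) and epsilon[n, s] (hartree)."""

    sigma: np.ndarray
    epsilon: np.ndarray
    env_indices: list[int]  # environment sites that carry LJ parameters

    @classmethod
    def build(
        cls, core: list[CoreAtom], env: list[EnvironmentSite]
    ) -> "LJPairTable":
        idx = [
            i
            for i, s in enumerate(env)
            if s.lj_sigma is not None and s.lj_epsilon is not None
        ]
        if len(idx) < len(env):
            warnings.warn(
                f"{len(env) - len(idx)} environment site(s) lack LJ parameters "
                "and are skipped in the Lennard-Jones terms",
                stacklevel=3,
            )
        sig_s = np.array([env[i].lj_sigma for i in idx])
        eps_s = np.array([env[i].lj_epsilon for i in idx])
        sig_n = np.array([a.lj_sigma for a in core])
        eps_n = np.array([a.lj_epsilon for a in core])
        sigma = 0.5 * (sig_n[:, None] + sig_s[None, :])
        epsilon = np.sqrt(eps_n[:, None] * eps_s[None, :])
        return cls(sigma=sigma, epsilon=epsilon, env_indices=idx)


def _pair_terms(r: float, sigma: float, epsilon: float) -> tuple[float, float, float]:
    """(E, dE/dr, d2E/dr2) for one pair."""
    if r < MIN_PAIR_DISTANCE:
        raise ValueError(f"LJ pair at singular distance {r:.3e} bohr")
    s6 = (sigma / r) ** 6
    s12 = s6 * s6
    e = 4.0 * epsilon * (s12 - s6)
    de = 4.0 * epsilon * (-12.0 * s12 + 6.0 * s6) / r
    d2e = 4.0 * epsilon * (156.0 * s12 - 42.0 * s6) / r**2
    return e, de, d2e


@dataclass
class LJReport:
    energy: float
    gradient: np.ndarray
    hessian: np.ndarray


def lj_report(
    core: list[CoreAtom],
    env: list[EnvironmentSite],
    derivatives: int = 2,
) -> LJReport:
    table = LJPairTable.build(core, env)
    n3 = 3 * len(core)
    energy = 0.0
    grad = np.zeros(n3)
    hess = np.zeros((n3, n3))
    eye = np.eye(3)
    for n, atom in enumerate(core):
        for k, si in enumerate(table.env_indices):
            eps = table.epsilon[n, k]
            if eps == 0.0:
                continue
            d = atom.position - env[si].position
            r = float(np.linalg.norm(d))
            e, de, d2e = _pair_terms(r, table.sigma[n, k], eps)
            energy += e
            if derivatives >= 1:
                u = d / r
                grad[3 * n : 3 * n + 3] += de * u
                if derivatives >= 2:
                    blk = d2e * np.outer(u, u) + (de / r) * (eye - np.outer(u, u))
                    hess[3 * n : 3 * n + 3, 3 * n : 3 * n + 3] += blk
    return LJReport(energy=energy, gradient=grad, hessian=hess)


def lj_energy(core: list[CoreAtom], env: list[EnvironmentSite]) -> float:
    return lj_report(core, env, derivatives=0).energy


def lj_gradient(core: list[CoreAtom], env: list[EnvironmentSite]) -> np.ndarray:
    return lj_report(core, env, derivatives=1).gradient


def lj_hessian(core: list[CoreAtom], env: list[EnvironmentSite]) -> np.ndarray:
    return lj_report(core, env, derivatives=2).hessian
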