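"""Combined embedding energy E_es + E_ind + E_LJ with analytic derivatives."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .electrostatics import electrostatic_report
from .induction import induction_report
from .lennard_jones import lj_report
from .system import CoreAtom, EnvironmentSite

__all__ = ["EnergyReport", "total_report", "total_energy", "total_gradient",
           "total_hessian"]


@dataclass
class EnergyReport:
    """Embedding energy decomposition with derivatives w.r.t. core coordinates."""

    e_es: float
    e_ind: float
    e_lj: float
    gradient: np.ndarray
    hessian: np.ndarray
    es_per_order: dict[int, float]

    @property
    def total(self) -> float:
        return self.e_es + self.e_ind + self.e_lj


def total_report(
    sites: list[EnvironmentSite],
    core: list[CoreAtom],
    derivatives: int = 2,
    induction_tol: float = 1e-10,
) -> EnergyReport:
    es = electrostatic_report(sites, core, derivatives=derivatives)
    ind = induction_report(sites, core, tol=induction_tol, derivatives=derivatives)
    lj = lj_report(core, sites, derivatives=derivatives)
    return EnergyReport(
        e_es=es.energy,
        e_ind=ind.energy,
        e_lj=lj.energy,
        gradient=es.gradient + ind.gradient + lj.gradient,
        hessian=es.hessian + ind.hessian + lj.hessian,
        es_per_order=es.per_order,
    )


def total_energy(sites: list[EnvironmentSite], core: list[CoreAtom]) -> float:
    return total_report(sites, core, derivatives=0).total


def total_gradient(sites: list[EnvironmentSite], core: list[CoreAtom]) -> np.ndarray:
    return total_report(sites, core, derivatives=1).gradient


def total_hessian(sites: list[EnvironmentSite], core: list[CoreAtom]) -> np.ndarray:
    return total_report(sites, core, derivatives=2).hessian
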