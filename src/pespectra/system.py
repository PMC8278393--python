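"""Domain types for embedded systems.

An embedded system consists of a *core* region, represented classically here
by point-charge nuclei with masses and optional Lennard-Jones parameters, and
an *environment* of fragments, each fragment carrying distributed sites with
permanent multipoles (charge, dipole, quadrupole), dipole–dipole
polarizabilities, and exclusion lists.  All positions and properties are
stored in Hartree atomic units.

Multipole components of order k are stored as length-(k+1)(k+2)/2 arrays in
the canonical x-major ordering of :func:`pespectra.multiindex.indices_of_order`
(order 2: xx, xy, xz, yy, yz, zz).  They are raw Cartesian moments
M^[α] = Σ_c q_c d_c^α; the 1/α! weights of the multipole expansion are
applied where the expansion is evaluated, not in storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnvironmentSite", "CoreAtom", "sites_positions", "core_positions"]

MAX_MULTIPOLE_ORDER = 2
_N_COMPONENTS = {0: 1, 1: 3, 2: 6}


@dataclass
class EnvironmentSite:
    """A classical environment site (position in bohr, properties in a.u.)."""

    position: np.ndarray
    fragment_id: int
    element: str = "X"
    multipoles: dict[int, np.ndarray] = field(default_factory=dict)
    polarizability: np.ndarray | None = None  # symmetric 3x3, bohr^3
    exclusions: frozenset[int] = frozenset()  # global site indices
    lj_sigma: float | None = None  # bohr
    lj_epsilon: float | None = None  # hartree

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        clean: dict[int, np.ndarray] = {}
        for order, comps in self.multipoles.items():
            if order not in _N_COMPONENTS:
                raise ValueError(
                    f"multipole order {order} unsupported (max {MAX_MULTIPOLE_ORDER})"
                )
            arr = np.asarray(comps, dtype=float).reshape(-1)
            if arr.size != _N_COMPONENTS[order]:
                raise ValueError(
                    f"order-{order} multipole needs {_N_COMPONENTS[order]} components,"
                    f" got {arr.size}"
                )
            clean[order] = arr
        self.multipoles = clean
        if self.polarizability is not None:
            a = np.asarray(self.polarizability, dtype=float).reshape(3, 3)
            if not np.allclose(a, a.T, atol=1e-10):
                raise ValueError("site polarizability must be symmetric")
            if np.linalg.eigvalsh(a).min() < -1e-10:
                raise ValueError("site polarizability must be positive semidefinite")
            self.polarizability = 0.5 * (a + a.T)
        self.exclusions = frozenset(int(i) for i in self.exclusions)

    @property
    def max_order(self) -> int:
        return max(self.multipoles, default=-1)

    @property
    def is_polarizable(self) -> bool:
        return self.polarizability is not None and np.any(self.polarizability != 0.0)

    def charge(self) -> float:
        q = self.multipoles.get(0)
        return float(q[0]) if q is not None else 0.0


@dataclass
class CoreAtom:
    """A nucleus of the (proxy) quantum region."""

    position: np.ndarray
    charge: float  # nuclear charge Z, e
    mass: float  # amu
    element: str = "X"
    lj_sigma: float = 0.0  # bohr
    lj_epsilon: float = 0.0  # hartree

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.charge <= 0:
            raise ValueError(f"nuclear charge must be > 0, got {self.charge}")
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError("LJ parameters must be >= 0")


def sites_positions(sites: list[EnvironmentSite]) -> np.ndarray:
    return np.array([s.position for s in sites]).reshape(-1, 3)


def core_positions(core: list[CoreAtom]) -> np.ndarray:
    return np.array([a.position for a in core]).reshape(-1, 3)


def excluded(si: int, sj: int, sites: list[EnvironmentSite]) -> bool:
    """True if the classical interaction between two sites is omitted.

    Same-fragment pairs are always excluded; explicit exclusion lists
    (symmetrized at read time) may extend this across fragments.
    """
    a, b = sites[si], sites[sj]
    if si == sj:
        return True
    if a.fragment_id == b.fragment_id:
        return True
    return sj in a.exclusions or si in b.exclusions


def fragment_ids(sites: list[EnvironmentSite]) -> list[int]:
    seen: list[int] = []
    for s in sites:
        if s.fragment_id not in seen:
            seen.append(s.fragment_id)
    return seen
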