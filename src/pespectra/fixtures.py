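"""Deterministic toy embedded systems for exercising the full pipeline.

The generator builds a small point-charge "core molecule" surrounded by
water-like fragments, each carrying site charges (summing to the template's
net charge), dipoles, quadrupoles and isotropic-with-slight-anisotropy
dipole–dipole polarizabilities — the content of a standard embedding
potential.  Defaults emulate a first solvation shell: fragments at 6–14 bohr
from the core, never closer than 3 bohr to any core atom.

Because the core is a classical proxy, an intramolecular potential is needed
to give it vibrations: a network of pair springs with equilibrium at the
template geometry and distance-weighted force constants, with analytic
gradient and Hessian.  Toy dipole and polarizability surfaces (point-charge
dipole plus environment induced dipoles; a bond-polarizability model) stand
in for the electronic property gradients that the double-harmonic intensity
expressions consume.  All of these are smooth, rotation-consistent, and
finite-difference-validated in the tests; none claims chemical accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import (
    ANGSTROM_TO_BOHR,
    ATOMIC_MASS_AMU,
    KJMOL_TO_HARTREE,
)
from .induction import (
    _field_first_derivative,
    assemble_response_matrix,
    solve_induced_moments,
    total_site_field,
)
from .io import write_potential, write_xyz
from .system import CoreAtom, EnvironmentSite

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "shell_filter",
    "core_spring_model",
    "toy_dipole_surface",
    "toy_polarizability_surface",
    "make_snapshots",
    "write_fixture",
]

MIN_CORE_SITE_DISTANCE = 3.0  # bohr
MIN_INTERFRAGMENT_DISTANCE = 2.5  # bohr


# --- templates --------------------------------------------------------------

def _water_template() -> list[EnvironmentSite]:
    """Water-like 3-site fragment in its local frame (O at origin)."""
    r_oh = 1.8088  # bohr
    half = np.deg2rad(104.52 / 2.0)
    h1 = r_oh * np.array([np.sin(half), 0.0, np.cos(half)])
    h2 = r_oh * np.array([-np.sin(half), 0.0, np.cos(half)])
    # charges sum to 0; fragment dipole ~0.7 e bohr along +z
    q_o, q_h = -0.67, 0.335
    sites = [
        EnvironmentSite(
            position=np.zeros(3),
            fragment_id=0,
            element="O",
            multipoles={
                0: [q_o],
                1: [0.0, 0.0, 0.18],
                2: [0.45, 0.0, 0.0, 0.38, 0.0, 0.52],
            },
            polarizability=np.diag([6.0, 5.4, 5.7]),
            lj_sigma=3.166 * ANGSTROM_TO_BOHR,
            lj_epsilon=0.650 * KJMOL_TO_HARTREE,
        ),
    ]
    for h in (h1, h2):
        u = h / np.linalg.norm(h)
        sites.append(
            EnvironmentSite(
                position=h,
                fragment_id=0,
                element="H",
                multipoles={0: [q_h], 1: (0.06 * u).tolist()},
                polarizability=np.eye(3) * 1.8,
                lj_sigma=1.2 * ANGSTROM_TO_BOHR,
                lj_epsilon=0.05 * KJMOL_TO_HARTREE,
            )
        )
    return sites


def _acetone_like_core() -> list[CoreAtom]:
    """Planar 4-center point-charge proxy of a carbonyl compound (bohr)."""
    geom = {
        "C": np.array([0.0, 0.0, 0.0]),  # carbonyl carbon
        "O": np.array([0.0, 0.0, 2.30]),
        "C1": np.array([2.42, 0.0, -1.33]),  # methyl-like centers
        "C2": np.array([-2.42, 0.0, -1.33]),
    }
    lj = {  # OPLS-like: sigma (angstrom), epsilon (kJ/mol)
        "C": (3.75, 0.43932), "O": (2.96, 0.87864),
        "C1": (3.91, 0.49371), "C2": (3.91, 0.49371),
    }
    atoms = []
    for name, pos in geom.items():
        el = name[0]
        sig, eps = lj[name]
        atoms.append(
            CoreAtom(
                position=pos,
                charge=float({"C": 6, "O": 8}[el]),
                mass=ATOMIC_MASS_AMU[el] if el != "C" or name == "C" else 15.0345,
                element=el,
                lj_sigma=sig * ANGSTROM_TO_BOHR,
                lj_epsilon=eps * KJMOL_TO_HARTREE,
            )
        )
    return atoms


#: partial charges for the toy dipole surface of the default core (sums to 0)
DEFAULT_CORE_PARTIAL_CHARGES = np.array([0.57, -0.47, -0.05, -0.05])


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a generated toy solvated system."""

    n_fragments: int = 8
    seed: int = 0
    shell_inner: float = 6.0  # bohr
    shell_outer: float = 14.0  # bohr
    max_multipole_order: int = 2

    def __post_init__(self) -> None:
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")
        if not 0 < self.shell_inner <= self.shell_outer:
            raise ValueError("need 0 < shell_inner <= shell_outer")
        if self.max_multipole_order not in (0, 1, 2):
            raise ValueError("max_multipole_order must be 0, 1 or 2")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _rotate_multipoles(
    multipoles: dict[int, np.ndarray], rot: np.ndarray
) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for order, comps in multipoles.items():
        if order == 0:
            out[0] = comps.copy()
        elif order == 1:
            out[1] = rot @ comps
        else:
            xx, xy, xz, yy, yz, zz = comps
            m = np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])
            m = rot @ m @ rot.T
            out[2] = np.array(
                [m[0, 0], m[0, 1], m[0, 2], m[1, 1], m[1, 2], m[2, 2]]
            )
    return out


def _place_fragment(
    template: list[EnvironmentSite],
    frag_id: int,
    rot: np.ndarray,
    shift: np.ndarray,
) -> list[EnvironmentSite]:
    out = []
    for s in template:
        out.append(
            replace(
                s,
                position=rot @ s.position + shift,
                fragment_id=frag_id,
                multipoles=_rotate_multipoles(s.multipoles, rot),
                polarizability=None
                if s.polarizability is None
                else rot @ s.polarizability @ rot.T,
            )
        )
    return out


def _truncate_orders(sites: list[EnvironmentSite], k_max: int) -> None:
    for s in sites:
        s.multipoles = {k: v for k, v in s.multipoles.items() if k <= k_max}


def make_fixture(
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[list[CoreAtom], list[EnvironmentSite]]:
    """Reproducible core + solvated-shell environment for a given seed."""
    rng = np.random.default_rng(spec.seed)
    core = _acetone_like_core()
    core_pos = np.array([a.position for a in core])
    sites: list[EnvironmentSite] = []
    placed_pos: list[np.ndarray] = []
    for frag in range(spec.n_fragments):
        for _attempt in range(500):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(spec.shell_inner, spec.shell_outer)
            shift = direction * radius
            rot = _random_rotation(rng)
            candidate = _place_fragment(_water_template(), frag, rot, shift)
            cand_pos = np.array([s.position for s in candidate])
            d_core = np.linalg.norm(
                cand_pos[:, None, :] - core_pos[None, :, :], axis=-1
            ).min()
            d_frag = (
                np.linalg.norm(
                    cand_pos[:, None, :] - np.array(placed_pos)[None, :, :],
                    axis=-1,
                ).min()
                if placed_pos
                else np.inf
            )
            if d_core >= MIN_CORE_SITE_DISTANCE and d_frag >= MIN_INTERFRAGMENT_DISTANCE:
                sites.extend(candidate)
                placed_pos.extend(cand_pos)
                break
        else:
            raise RuntimeError(
                f"could not place fragment {frag}; widen the shell radii"
            )
    _truncate_orders(sites, spec.max_multipole_order)
    return core, sites


def shell_filter(
    sites: list[EnvironmentSite],
    center: np.ndarray,
    cutoff_radius: float,
) -> list[EnvironmentSite]:
    """Keep whole fragments whose center of mass lies within the cutoff."""
    center = np.asarray(center, float)
    frags: dict[int, list[EnvironmentSite]] = {}
    for s in sites:
        frags.setdefault(s.fragment_id, []).append(s)
    kept: list[EnvironmentSite] = []
    for fid in sorted(frags):
        members = frags[fid]
        masses = np.array(
            [ATOMIC_MASS_AMU.get(s.element, 1.0) for s in members]
        )
        com = masses @ np.array([s.position for s in members]) / masses.sum()
        if np.linalg.norm(com - center) <= cutoff_radius:
            kept.extend(members)
    return kept


# --- toy intramolecular potential ------------------------------------------

@dataclass
class SpringModel:
    """All-pairs harmonic springs with equilibrium at a reference geometry."""

    reference: np.ndarray  # (N, 3) bohr
    force_constants: np.ndarray  # (N, N) hartree/bohr^2, zero diagonal
    rest_lengths: np.ndarray  # (N, N) bohr

    def energy(self, positions: np.ndarray) -> float:
        return self._report(positions, derivatives=0)[0]

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        return self._report(positions, derivatives=1)[1]

    def hessian(self, positions: np.ndarray) -> np.ndarray:
        return self._report(positions, derivatives=2)[2]

    def _report(self, positions: np.ndarray, derivatives: int = 2):
        pos = np.asarray(positions, float).reshape(-1, 3)
        n = pos.shape[0]
        e = 0.0
        grad = np.zeros(3 * n)
        hess = np.zeros((3 * n, 3 * n))
        eye = np.eye(3)
        for i in range(n):
            for j in range(i + 1, n):
                k = self.force_constants[i, j]
                if k == 0.0:
                    continue
                d = pos[i] - pos[j]
                r = float(np.linalg.norm(d))
                dr = r - self.rest_lengths[i, j]
                e += 0.5 * k * dr * dr
                if derivatives >= 1:
                    u = d / r
                    g = k * dr * u
                    grad[3 * i : 3 * i + 3] += g
                    grad[3 * j : 3 * j + 3] -= g
                    if derivatives >= 2:
                        blk = k * np.outer(u, u) + (k * dr / r) * (
                            eye - np.outer(u, u)
                        )
                        for a, b, sgn in ((i, i, 1), (j, j, 1), (i, j, -1), (j, i, -1)):
                            hess[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] += sgn * blk
        return e, grad, hess


def core_spring_model(
    core: list[CoreAtom], stiffness: float = 8.0
) -> SpringModel:
    """Distance-weighted springs k_ij = stiffness / r_ij³ (hartree/bohr²).

    Equilibrium at the current geometry, so the template is a stationary
    point; nearest neighbours dominate, giving bond-like stiff modes.
    """
    pos = np.array([a.position for a in core])
    n = pos.shape[0]
    rest = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    k = np.zeros((n, n))
    mask = ~np.eye(n, dtype=bool)
    k[mask] = stiffness / rest[mask] ** 3
    return SpringModel(reference=pos, force_constants=k, rest_lengths=rest)


# --- toy property surfaces ---------------------------------------------------

def toy_dipole_surface(
    core: list[CoreAtom],
    sites: list[EnvironmentSite] | None = None,
    charges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dipole μ = Σ q_n R_n (+ environment induced dipoles) and its gradient.

    Returns (mu (3,), dmu (3N, 3)) in atomic units, with
    dmu[3n+g, a] = ∂μ_a/∂R_{n,g}.  The point-charge part uses `charges`
    (defaults to the nuclear charges); the environment part is the sum of the
    induced dipoles, whose response to core motion is obtained analytically
    from the linear-response matrix.
    """
    q = (
        np.array([a.charge for a in core])
        if charges is None
        else np.asarray(charges, float)
    )
    pos = np.array([a.position for a in core])
    n = len(core)
    mu = q @ pos
    dmu = np.zeros((3 * n, 3))
    for i in range(n):
        for g in range(3):
            dmu[3 * i + g, g] = q[i]
    if sites:
        response = assemble_response_matrix(sites)
        if response.n_sites:
            fld = total_site_field(sites, core)
            induced = solve_induced_moments(response, fld)
            mu = mu + induced.moments.reshape(-1, 3).sum(axis=0)
            dF = _field_first_derivative(response, sites, core)  # (3S, 3N)
            X = np.linalg.solve(response.matrix, dF)  # dμ_sites/dR
            dmu += X.reshape(-1, 3, 3 * n).sum(axis=0).T
    return mu, dmu


@dataclass(frozen=True)
class BondPolarizabilityParams:
    """Bond-polarizability model parameters (atomic units)."""

    atom_isotropic: float = 8.0  # bohr^3 per atom
    longitudinal: float = 0.9  # c_l: alpha_parallel = c_l * r^2
    transverse: float = 0.5  # c_t: alpha_perp = c_t * r
    max_bond_length: float = 3.5  # bohr; longer pairs are not bonds


def toy_polarizability_surface(
    core: list[CoreAtom],
    params: BondPolarizabilityParams = BondPolarizabilityParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Bond-polarizability α(R) and analytic gradient.

    α = Σ_atoms c_iso·I + Σ_bonds [ α_t(r)·I + (α_l(r) − α_t(r))·ûûᵀ ]
    with α_l = c_l r², α_t = c_t r.  Returns (alpha (3,3), dalpha (3N,3,3))
    with dalpha[3n+g] = ∂α/∂R_{n,g}; the model is exactly rotation
    equivariant, α(Rot·R) = Rot·α(R)·Rotᵀ.
    """
    pos = np.array([a.position for a in core])
    n = pos.shape[0]
    alpha = params.atom_isotropic * n * np.eye(3)
    dalpha = np.zeros((3 * n, 3, 3))
    eye = np.eye(3)
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            r = float(np.linalg.norm(d))
            if r > params.max_bond_length:
                continue
            u = d / r
            P = np.outer(u, u)
            a_l, a_t = params.longitudinal * r * r, params.transverse * r
            alpha += a_t * eye + (a_l - a_t) * P
            da_l, da_t = 2.0 * params.longitudinal * r, params.transverse
            for g in range(3):
                e_g = eye[g]
                dP = (np.outer(e_g, u) + np.outer(u, e_g) - 2.0 * u[g] * P) / r
                term = (
                    da_t * u[g] * eye
                    + (da_l - da_t) * u[g] * P
                    + (a_l - a_t) * dP
                )
                dalpha[3 * i + g] += term
                dalpha[3 * j + g] -= term
    return alpha, dalpha


# --- snapshot ensembles ------------------------------------------------------

def make_snapshots(
    spec: FixtureSpec,
    n: int,
    jitter_scale: float,
    seed: int | None = None,
) -> list[tuple[list[CoreAtom], list[EnvironmentSite]]]:
    """n jittered copies of a fixture: Gaussian core displacements plus
    rigid-body displacement of each fragment (both with std jitter_scale, bohr)."""
    core, sites = make_fixture(spec)
    rng = np.random.default_rng(spec.seed + 7919 if seed is None else seed)
    out = []
    frag_ids = sorted({s.fragment_id for s in sites})
    for _ in range(n):
        jcore = [
            replace(a, position=a.position + jitter_scale * rng.normal(size=3))
            for a in core
        ]
        shifts = {fid: jitter_scale * rng.normal(size=3) for fid in frag_ids}
        jsites = [
            replace(s, position=s.position + shifts[s.fragment_id]) for s in sites
        ]
        out.append((jcore, jsites))
    return out


def write_fixture(
    core: list[CoreAtom],
    sites: list[EnvironmentSite],
    directory: str | Path,
    name: str = "fixture",
    spec: FixtureSpec | None = None,
) -> dict[str, str]:
    """Emit .pot + .xyz + JSON manifest; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pot = directory / f"{name}.pot"
    xyz = directory / f"{name}.xyz"
    manifest = directory / f"{name}.json"
    write_potential(sites, pot)
    write_xyz([a.element for a in core],
              np.array([a.position for a in core]), xyz,
              comment=f"pespectra fixture '{name}'")
    meta = {
        "name": name,
        "n_core_atoms": len(core),
        "n_sites": len(sites),
        "n_fragments": len({s.fragment_id for s in sites}),
        "core_charges": [a.charge for a in core],
        "core_masses": [a.mass for a in core],
        "core_lj_sigma_bohr": [a.lj_sigma for a in core],
        "core_lj_epsilon_hartree": [a.lj_epsilon for a in core],
        "potential": pot.name,
        "geometry": xyz.name,
    }
    if spec is not None:
        meta["spec"] = {
            "n_fragments": spec.n_fragments,
            "seed": spec.seed,
            "shell_inner": spec.shell_inner,
            "shell_outer": spec.shell_outer,
            "max_multipole_order": spec.max_multipole_order,
        }
    manifest.write_text(json.dumps(meta, indent=1))
    return {"potential": str(pot), "geometry": str(xyz), "manifest": str(manifest)}
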