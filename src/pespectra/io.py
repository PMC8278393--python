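"""File formats: PE potentials (.pot), XYZ geometries, LJ tables, property dumps.

The potential-file dialect is the Dalton/PyFraME-style sectioned text format:

    @COORDINATES
    <n_sites>
    AA | AU
    <element> <x> <y> <z>            (one line per site)
    @MULTIPOLES
    ORDER 0
    <count>
    <site> <q>
    ORDER 1
    <count>
    <site> <mu_x> <mu_y> <mu_z>
    ORDER 2
    <count>
    <site> <xx> <xy> <xz> <yy> <yz> <zz>
    @POLARIZABILITIES
    ORDER 1 1
    <count>
    <site> <xx> <xy> <xz> <yy> <yz> <zz>
    EXCLISTS
    <n_rows> <row_length>
    <site> <other> ... (0-padded)

Site indices are 1-based on disk.  Coordinates may be ångström (AA) or bohr
(AU) on disk; memory is always bohr.  Exclusion rows are symmetrized and
validated for reciprocity; fragments are inferred as connected components of
the exclusion graph (isolated sites form their own fragments).

Everything else (XYZ, whitespace LJ tables, the property-matrix dump) is
plain text as documented on the writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import (
    ANGSTROM_TO_BOHR,
    BOHR_TO_ANGSTROM,
    KCALMOL_TO_HARTREE,
    KJMOL_TO_HARTREE,
)
from .system import CoreAtom, EnvironmentSite

__all__ = [
    "PotentialParseError",
    "PropertyDump",
    "read_potential",
    "write_potential",
    "read_xyz",
    "write_xyz",
    "read_lj_table",
    "assign_lj_parameters",
    "read_property_dump",
    "write_property_dump",
]


class PotentialParseError(ValueError):
    """Malformed or unsupported potential-file content."""


_N_COMP = {0: 1, 1: 3, 2: 6}


def _tokens(path: Path) -> list[tuple[int, str]]:
    out = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if line:
            out.append((ln, line))
    return out


def read_potential(path: str | Path) -> list[EnvironmentSite]:
    """Parse a .pot file into environment sites (positions in bohr)."""
    path = Path(path)
    lines = _tokens(path)
    pos = 0

    def peek() -> tuple[int, str] | None:
        return lines[pos] if pos < len(lines) else None

    def advance() -> tuple[int, str]:
        nonlocal pos
        if pos >= len(lines):
            raise PotentialParseError(f"{path}: unexpected end of file")
        item = lines[pos]
        pos += 1
        return item

    coords: list[np.ndarray] | None = None
    elements: list[str] = []
    multipoles: dict[int, dict[int, np.ndarray]] = {}
    polar: dict[int, np.ndarray] = {}
    excl: dict[int, set[int]] = {}

    while (item := peek()) is not None:
        ln, line = item
        key = line.upper()
        if key == "@COORDINATES":
            advance()
            n = int(advance()[1])
            unit = advance()[1].upper()
            if unit not in ("AA", "AU"):
                raise PotentialParseError(f"{path}:{ln}: unknown unit '{unit}'")
            scale = ANGSTROM_TO_BOHR if unit == "AA" else 1.0
            coords = []
            for _ in range(n):
                lno, row = advance()
                parts = row.split()
                if len(parts) != 4:
                    raise PotentialParseError(
                        f"{path}:{lno}: coordinate line needs 'element x y z'"
                    )
                elements.append(parts[0])
                coords.append(np.array([float(v) for v in parts[1:]]) * scale)
        elif key == "@MULTIPOLES":
            advance()
            while (nxt := peek()) is not None and nxt[1].upper().startswith("ORDER"):
                lno, hdr = advance()
                order = int(hdr.split()[1])
                if order > 2:
                    raise PotentialParseError(
                        f"{path}:{lno}: multipole order {order} unsupported (max 2)"
                    )
                count = int(advance()[1])
                for _ in range(count):
                    lno2, row = advance()
                    parts = row.split()
                    if len(parts) != 1 + _N_COMP[order]:
                        raise PotentialParseError(
                            f"{path}:{lno2}: order-{order} row needs "
                            f"{_N_COMP[order]} components"
                        )
                    sid = int(parts[0]) - 1
                    multipoles.setdefault(sid, {})[order] = np.array(
                        [float(v) for v in parts[1:]]
                    )
        elif key == "@POLARIZABILITIES":
            advance()
            lno, hdr = advance()
            if hdr.upper().split() != ["ORDER", "1", "1"]:
                raise PotentialParseError(
                    f"{path}:{lno}: only ORDER 1 1 (dipole-dipole) "
                    "polarizabilities are supported"
                )
            count = int(advance()[1])
            for _ in range(count):
                lno2, row = advance()
                parts = row.split()
                if len(parts) != 7:
                    raise PotentialParseError(
                        f"{path}:{lno2}: polarizability row needs 6 components"
                    )
                sid = int(parts[0]) - 1
                xx, xy, xz, yy, yz, zz = (float(v) for v in parts[1:])
                polar[sid] = np.array(
                    [[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]]
                )
        elif key == "EXCLISTS":
            advance()
            lno, hdr = advance()
            n_rows, row_len = (int(v) for v in hdr.split())
            for _ in range(n_rows):
                lno2, row = advance()
                vals = [int(v) for v in row.split()]
                if len(vals) != row_len:
                    raise PotentialParseError(
                        f"{path}:{lno2}: exclusion row has {len(vals)} entries,"
                        f" expected {row_len}"
                    )
                sid = vals[0] - 1
                excl.setdefault(sid, set()).update(
                    v - 1 for v in vals[1:] if v > 0
                )
        else:
            raise PotentialParseError(f"{path}:{ln}: unknown section '{line}'")

    if coords is None:
        raise PotentialParseError(f"{path}: missing @COORDINATES section")
    n = len(coords)
    for sid in list(multipoles) + list(polar) + list(excl):
        if not 0 <= sid < n:
            raise PotentialParseError(
                f"{path}: site index {sid + 1} outside declared count {n}"
            )
    # symmetrize exclusions and validate reciprocity
    for sid, others in list(excl.items()):
        for o in others:
            excl.setdefault(o, set())
            if sid not in excl[o]:
                excl[o].add(sid)
    # fragments = connected components of the exclusion graph
    fragment_of = [-1] * n
    next_frag = 0
    for start in range(n):
        if fragment_of[start] != -1:
            continue
        stack = [start]
        while stack:
            s = stack.pop()
            if fragment_of[s] != -1:
                continue
            fragment_of[s] = next_frag
            stack.extend(excl.get(s, ()))
        next_frag += 1

    sites = []
    for i in range(n):
        sites.append(
            EnvironmentSite(
                position=coords[i],
                fragment_id=fragment_of[i],
                element=elements[i],
                multipoles=multipoles.get(i, {}),
                polarizability=polar.get(i),
                exclusions=frozenset(excl.get(i, ())),
            )
        )
    return sites


def write_potential(sites: list[EnvironmentSite], path: str | Path) -> None:
    """Inverse of :func:`read_potential` (AU coordinates on disk)."""
    path = Path(path)
    order = sorted(range(len(sites)), key=lambda i: (sites[i].fragment_id, i))
    new_index = {old: new for new, old in enumerate(order)}
    lines = ["! PE potential written by pespectra", "@COORDINATES",
             str(len(sites)), "AU"]
    for i in order:
        s = sites[i]
        lines.append(
            f"{s.element:<2s} " + " ".join(f"{v: .12e}" for v in s.position)
        )
    lines.append("@MULTIPOLES")
    for k in (0, 1, 2):
        rows = [
            (new_index[i] + 1, sites[i].multipoles[k])
            for i in order
            if k in sites[i].multipoles
        ]
        if rows:
            lines.append(f"ORDER {k}")
            lines.append(str(len(rows)))
            for sid, comps in sorted(rows):
                lines.append(
                    f"{sid} " + " ".join(f"{v: .12e}" for v in comps)
                )
    pol_rows = []
    for i in order:
        s = sites[i]
        if s.polarizability is not None:
            a = s.polarizability
            pol_rows.append(
                (new_index[i] + 1,
                 [a[0, 0], a[0, 1], a[0, 2], a[1, 1], a[1, 2], a[2, 2]])
            )
    if pol_rows:
        lines.append("@POLARIZABILITIES")
        lines.append("ORDER 1 1")
        lines.append(str(len(pol_rows)))
        for sid, comps in sorted(pol_rows):
            lines.append(f"{sid} " + " ".join(f"{v: .12e}" for v in comps))
    # exclusion rows: same-fragment plus explicit lists
    frag_members: dict[int, list[int]] = {}
    for i in order:
        frag_members.setdefault(sites[i].fragment_id, []).append(new_index[i])
    rows = []
    for i in order:
        s = sites[i]
        others = {new_index[j] for j in s.exclusions}
        others |= {m for m in frag_members[s.fragment_id] if m != new_index[i]}
        rows.append([new_index[i] + 1] + sorted(o + 1 for o in others))
    width = max(len(r) for r in rows) if rows else 1
    lines.append("EXCLISTS")
    lines.append(f"{len(rows)} {width}")
    for r in rows:
        lines.append(" ".join(str(v) for v in r + [0] * (width - len(r))))
    path.write_text("\n".join(lines) + "\n")


# --- XYZ --------------------------------------------------------------------

def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray, str]:
    """Standard XYZ (ångström on disk); returns (elements, coords in bohr, comment)."""
    path = Path(path)
    raw = path.read_text().splitlines()
    try:
        n = int(raw[0].strip())
    except (IndexError, ValueError) as exc:
        raise PotentialParseError(f"{path}:1: malformed atom count") from exc
    comment = raw[1] if len(raw) > 1 else ""
    if len(raw) < 2 + n:
        raise PotentialParseError(f"{path}: declared {n} atoms, file too short")
    elements, coords = [], []
    for i, line in enumerate(raw[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise PotentialParseError(f"{path}:{i}: atom line needs 'element x y z'")
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return elements, np.asarray(coords) * ANGSTROM_TO_BOHR, comment


def write_xyz(
    elements: list[str], coords_bohr: np.ndarray, path: str | Path,
    comment: str = "",
) -> None:
    coords = np.asarray(coords_bohr).reshape(-1, 3) * BOHR_TO_ANGSTROM
    lines = [str(len(elements)), comment]
    for el, xyz in zip(elements, coords):
        lines.append(f"{el:<2s} " + " ".join(f"{v: .10f}" for v in xyz))
    Path(path).write_text("\n".join(lines) + "\n")


# --- LJ parameter tables ----------------------------------------------------

_LENGTH_UNITS = {"angstrom": ANGSTROM_TO_BOHR, "bohr": 1.0}
_ENERGY_UNITS = {
    "kjmol": KJMOL_TO_HARTREE,
    "kcalmol": KCALMOL_TO_HARTREE,
    "hartree": 1.0,
}


def read_lj_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Whitespace table 'element sigma epsilon' with a '# units: <len> <energy>' header.

    Returns element → (sigma in bohr, epsilon in hartree).
    """
    path = Path(path)
    length_f = energy_f = None
    table: dict[str, tuple[float, float]] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip().lower()
            if body.startswith("units:"):
                parts = body.split(":", 1)[1].split()
                if len(parts) != 2 or parts[0] not in _LENGTH_UNITS \
                        or parts[1] not in _ENERGY_UNITS:
                    raise PotentialParseError(
                        f"{path}:{ln}: units header must name a length "
                        f"({'/'.join(_LENGTH_UNITS)}) and an energy "
                        f"({'/'.join(_ENERGY_UNITS)})"
                    )
                length_f = _LENGTH_UNITS[parts[0]]
                energy_f = _ENERGY_UNITS[parts[1]]
            continue
        if length_f is None:
            raise PotentialParseError(
                f"{path}:{ln}: data before the mandatory '# units:' header"
            )
        parts = line.split()
        if len(parts) != 3:
            raise PotentialParseError(
                f"{path}:{ln}: expected 'element sigma epsilon'"
            )
        table[parts[0]] = (float(parts[1]) * length_f, float(parts[2]) * energy_f)
    return table


def assign_lj_parameters(
    objs: list[CoreAtom] | list[EnvironmentSite],
    table: dict[str, tuple[float, float]],
) -> None:
    """Set lj_sigma/lj_epsilon in place from an element-keyed table."""
    for o in objs:
        if o.element in table:
            o.lj_sigma, o.lj_epsilon = table[o.element]


# --- property dumps ---------------------------------------------------------

@dataclass
class PropertyDump:
    """Externally computed property matrices for a core geometry (a.u. + amu)."""

    elements: list[str]
    geometry: np.ndarray  # (N, 3) bohr
    masses: np.ndarray  # (N,) amu
    hessian: np.ndarray  # (3N, 3N) hartree/bohr^2
    dipole_gradient: np.ndarray | None = None  # (3N, 3) e
    polarizability_gradient: np.ndarray | None = None  # (3N, 6) packed symmetric

    def __post_init__(self) -> None:
        n = len(self.elements)
        self.geometry = np.asarray(self.geometry, float).reshape(n, 3)
        self.masses = np.asarray(self.masses, float).reshape(n)
        h = np.asarray(self.hessian, float)
        if h.shape != (3 * n, 3 * n):
            raise ValueError(
                f"Hessian shape {h.shape} inconsistent with {n} atoms"
            )
        scale = max(np.abs(h).max(), 1.0)
        if np.abs(h - h.T).max() > 1e-10 * scale:
            raise ValueError("Hessian is not symmetric")
        self.hessian = h
        if self.dipole_gradient is not None:
            d = np.asarray(self.dipole_gradient, float)
            if d.shape != (3 * n, 3):
                raise ValueError(f"dipole gradient shape {d.shape} != ({3*n}, 3)")
            self.dipole_gradient = d
        if self.polarizability_gradient is not None:
            p = np.asarray(self.polarizability_gradient, float)
            if p.shape != (3 * n, 6):
                raise ValueError(
                    f"polarizability gradient shape {p.shape} != ({3*n}, 6)"
                )
            self.polarizability_gradient = p


def write_property_dump(dump: PropertyDump, path: str | Path) -> None:
    n = len(dump.elements)
    lines = ["PESPECTRA PROPERTY DUMP V1", f"NATOMS {n}", "GEOMETRY bohr"]
    for el, xyz in zip(dump.elements, dump.geometry):
        lines.append(f"{el:<2s} " + " ".join(f"{v: .15e}" for v in xyz))
    lines.append("MASSES amu")
    lines.append(" ".join(f"{m:.10f}" for m in dump.masses))

    def emit(tag: str, mat: np.ndarray) -> None:
        lines.append(f"{tag} {mat.shape[0]} {mat.shape[1]}")
        for row in mat:
            lines.append(" ".join(f"{v: .15e}" for v in row))

    emit("HESSIAN", dump.hessian)
    if dump.dipole_gradient is not None:
        emit("DIPOLE_GRADIENT", dump.dipole_gradient)
    if dump.polarizability_gradient is not None:
        emit("POLARIZABILITY_GRADIENT", dump.polarizability_gradient)
    Path(path).write_text("\n".join(lines) + "\n")


def read_property_dump(path: str | Path) -> PropertyDump:
    path = Path(path)
    raw = [l for l in path.read_text().splitlines() if l.strip()]
    if not raw or raw[0].strip() != "PESPECTRA PROPERTY DUMP V1":
        raise PotentialParseError(f"{path}: not a pespectra property dump")
    i = 1
    if not raw[i].startswith("NATOMS"):
        raise PotentialParseError(f"{path}: missing NATOMS header")
    n = int(raw[i].split()[1])
    i += 1
    if not raw[i].startswith("GEOMETRY"):
        raise PotentialParseError(f"{path}: missing GEOMETRY section")
    i += 1
    elements, coords = [], []
    for _ in range(n):
        parts = raw[i].split()
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
        i += 1
    if not raw[i].startswith("MASSES"):
        raise PotentialParseError(f"{path}: missing MASSES section")
    i += 1
    masses = np.array([float(v) for v in raw[i].split()])
    i += 1
    mats: dict[str, np.ndarray] = {}
    while i < len(raw):
        parts = raw[i].split()
        tag, rows, cols = parts[0], int(parts[1]), int(parts[2])
        i += 1
        data = [[float(v) for v in raw[i + r].split()] for r in range(rows)]
        i += rows
        mat = np.asarray(data)
        if mat.shape != (rows, cols):
            raise PotentialParseError(f"{path}: {tag} block has wrong shape")
        mats[tag] = mat
    if "HESSIAN" not in mats:
        raise PotentialParseError(f"{path}: missing HESSIAN block")
    return PropertyDump(
        elements=elements,
        geometry=np.asarray(coords),
        masses=masses,
        hessian=mats["HESSIAN"],
        dipole_gradient=mats.get("DIPOLE_GRADIENT"),
        polarizability_gradient=mats.get("POLARIZABILITY_GRADIENT"),
    )
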