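"""Multi-index algebra and Cartesian interaction tensors.

A multi-index α = (ax, ay, az) of non-negative integers encodes the order of
a mixed Cartesian derivative; |α| = ax+ay+az is its total order, α! the
product of component factorials, and R^α the monomial Rx^ax Ry^ay Rz^az.
Sums over |α| run over all multi-indices of each total order, which keeps
multipole-order expressions open-ended.

The interaction tensor adopted throughout the package is

    T^[α](R_i, R_j) = ∂^α/∂R_j^α  1/|R_i − R_j|,

i.e. the α-th Cartesian derivative of the Coulomb kernel taken at the second
argument.  All downstream sign conventions (multipole energies, fields,
induced-dipole couplings) are fixed relative to this choice and verified
against explicit point-charge limits in the test suite.

Evaluation uses the point-charge limit of the McMurchie–Davidson auxiliary
recurrence: with R = R_j − R_i and r = |R|,

    R^n_{0,0,0} = (−1)^n (2n−1)!! / r^{2n+1}
    R^n_{t+1,u,v} = t R^{n+1}_{t−1,u,v} + x R^{n+1}_{t,u,v}   (same for u, v)

and T^[(t,u,v)] = R^0_{t,u,v}.  The recurrence is numerically stable for the
orders needed here (≤ 6 plus two geometric derivatives).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial
from typing import Iterator

import numpy as np

__all__ = [
    "MultiIndex",
    "enumerate_multiindices",
    "mi_factorial",
    "mi_power",
    "interaction_tensor",
    "tensor_block",
    "tensor_table",
    "InteractionTensorSet",
]

MAX_SUPPORTED_ORDER = 8


@dataclass(frozen=True, order=True)
class MultiIndex:
    """Triple of Cartesian derivative counts."""

    ax: int
    ay: int
    az: int

    def __post_init__(self) -> None:
        if min(self.ax, self.ay, self.az) < 0:
            raise ValueError(f"multi-index components must be >= 0, got {self}")

    @property
    def order(self) -> int:
        """|α| = ax + ay + az."""
        return self.ax + self.ay + self.az

    def factorial(self) -> int:
        """α! = ax!·ay!·az!."""
        return factorial(self.ax) * factorial(self.ay) * factorial(self.az)

    def __add__(self, other: "MultiIndex") -> "MultiIndex":
        return MultiIndex(self.ax + other.ax, self.ay + other.ay, self.az + other.az)

    def __sub__(self, other: "MultiIndex") -> "MultiIndex":
        return MultiIndex(self.ax - other.ax, self.ay - other.ay, self.az - other.az)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.ax, self.ay, self.az)

    def __iter__(self) -> Iterator[int]:
        return iter((self.ax, self.ay, self.az))


#: unit multi-indices along x, y, z
UNIT = (MultiIndex(1, 0, 0), MultiIndex(0, 1, 0), MultiIndex(0, 0, 1))


@lru_cache(maxsize=None)
def _indices_of_order(k: int) -> tuple[MultiIndex, ...]:
    out = [
        MultiIndex(ax, ay, k - ax - ay)
        for ax in range(k, -1, -1)
        for ay in range(k - ax, -1, -1)
    ]
    return tuple(out)


def enumerate_multiindices(max_order: int) -> list[MultiIndex]:
    """All multi-indices with 0 ≤ |α| ≤ max_order.

    Grouped by ascending |α|; within each group ordered with x-count
    descending then y-count descending, so order 1 reads (1,0,0), (0,1,0),
    (0,0,1) and order 2 reads xx, xy, xz, yy, yz, zz — the component order
    used on disk for dipoles, quadrupoles and polarizabilities.
    """
    if max_order < 0:
        raise ValueError(f"max_order must be >= 0, got {max_order}")
    out: list[MultiIndex] = []
    for k in range(max_order + 1):
        out.extend(_indices_of_order(k))
    return out


def indices_of_order(k: int) -> tuple[MultiIndex, ...]:
    """The (k+1)(k+2)/2 multi-indices with |α| = k, in canonical order."""
    if k < 0:
        raise ValueError(f"order must be >= 0, got {k}")
    return _indices_of_order(k)


def mi_factorial(alpha: MultiIndex) -> int:
    return alpha.factorial()


def mi_power(R: np.ndarray, alpha: MultiIndex) -> float:
    """R^α = Rx^ax · Ry^ay · Rz^az."""
    R = np.asarray(R, dtype=float)
    return float(R[0] ** alpha.ax * R[1] ** alpha.ay * R[2] ** alpha.az)


class CoincidentPointsError(ValueError):
    """Interaction tensor requested at (numerically) coincident points."""


MIN_SEPARATION = 1e-6  # bohr; closer pairs are treated as singular


def tensor_table(R_i: np.ndarray, R_j: np.ndarray, max_order: int) -> dict[tuple[int, int, int], float]:
    """All T^[α](R_i, R_j) for 0 ≤ |α| ≤ max_order in one recurrence sweep."""
    if not 0 <= max_order <= MAX_SUPPORTED_ORDER:
        raise ValueError(f"order must be in [0, {MAX_SUPPORTED_ORDER}], got {max_order}")
    R = np.asarray(R_j, dtype=float) - np.asarray(R_i, dtype=float)
    r2 = float(R @ R)
    if r2 < MIN_SEPARATION**2:
        raise CoincidentPointsError(
            f"interaction tensor undefined for separation {np.sqrt(r2):.3e} bohr"
        )
    x, y, z = (float(c) for c in R)
    inv_r2 = 1.0 / r2
    # base line R^n_{000} = (-1)^n (2n-1)!! / r^(2n+1)
    base = [r2 ** -0.5]
    for n in range(1, max_order + 1):
        base.append(-base[-1] * (2 * n - 1) * inv_r2)
    # aux[(t,u,v)] at auxiliary level n, built downward from n = max_order
    aux: dict[tuple[int, int, int], float] = {(0, 0, 0): base[max_order]}
    for n in range(max_order - 1, -1, -1):
        prev = aux
        aux = {(0, 0, 0): base[n]}
        for k in range(max_order - n):
            for idx in _indices_of_order(k):
                t, u, v = idx.as_tuple()
                val = prev[(t, u, v)]
                aux[(t + 1, u, v)] = (t * prev[(t - 1, u, v)] if t else 0.0) + x * val
                aux[(t, u + 1, v)] = (u * prev[(t, u - 1, v)] if u else 0.0) + y * val
                aux[(t, u, v + 1)] = (v * prev[(t, u, v - 1)] if v else 0.0) + z * val
    return aux


def interaction_tensor(R_i: np.ndarray, R_j: np.ndarray, alpha: MultiIndex) -> float:
    """Single component T^[α](R_i, R_j) = ∂^α_{R_j} 1/|R_i − R_j|."""
    return tensor_table(R_i, R_j, alpha.order)[alpha.as_tuple()]


@dataclass(frozen=True)
class InteractionTensorSet:
    """All components of a given order for one point pair (atomic units)."""

    R_i: tuple[float, float, float]
    R_j: tuple[float, float, float]
    order: int
    components: dict[tuple[int, int, int], float]

    def __getitem__(self, alpha: MultiIndex | tuple[int, int, int]) -> float:
        key = alpha.as_tuple() if isinstance(alpha, MultiIndex) else alpha
        return self.components[key]

    def as_array(self) -> np.ndarray:
        """Components in canonical (x-major) order."""
        return np.array(
            [self.components[a.as_tuple()] for a in _indices_of_order(self.order)]
        )


def tensor_block(R_i: np.ndarray, R_j: np.ndarray, order: int) -> InteractionTensorSet:
    """The complete order-`order` tensor set for the pair (R_i, R_j)."""
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    table = tensor_table(R_i, R_j, order)
    comps = {a.as_tuple(): table[a.as_tuple()] for a in _indices_of_order(order)}
    return InteractionTensorSet(
        tuple(float(c) for c in np.asarray(R_i, float)),
        tuple(float(c) for c in np.asarray(R_j, float)),
        order,
        comps,
    )


def dipole_dipole_tensor(R_i: np.ndarray, R_j: np.ndarray) -> np.ndarray:
    """Order-2 tensor as a symmetric 3×3 matrix, T2_ab = ∂_a ∂_b (1/r)."""
    t = tensor_table(R_i, R_j, 2)
    return np.array(
        [
            [t[(2, 0, 0)], t[(1, 1, 0)], t[(1, 0, 1)]],
            [t[(1, 1, 0)], t[(0, 2, 0)], t[(0, 1, 1)]],
            [t[(1, 0, 1)], t[(0, 1, 1)], t[(0, 0, 2)]],
        ]
    )
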