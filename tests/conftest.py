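"""Shared fixtures: small embedded systems generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pespectra.fixtures import FixtureSpec, make_fixture


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def small_system():
    """A 5-fragment toy solvated system (15 sites, 4 core atoms)."""
    return make_fixture(FixtureSpec(n_fragments=5, seed=11))


@pytest.fixture
def vacuum_core():
    core, _ = make_fixture(FixtureSpec(n_fragments=0, seed=0))
    return core


def central_fd_gradient(func, positions_objs, step=1e-4, richardson=True):
    """Central finite differences of a scalar function of core positions.

    `positions_objs` are objects with a mutable .position array; the function
    is re-evaluated with single coordinates displaced.  With richardson=True
    the h and h/2 estimates are combined to cancel the O(h^2) term.
    """
    n3 = 3 * len(positions_objs)
    out = np.zeros(n3)
    for i, obj in enumerate(positions_objs):
        for g in range(3):
            orig = obj.position[g]

            def df(h):
                obj.position[g] = orig + h
                ep = func()
                obj.position[g] = orig - h
                em = func()
                obj.position[g] = orig
                return (ep - em) / (2 * h)

            if richardson:
                d1, d2 = df(step), df(step / 2)
                out[3 * i + g] = (4 * d2 - d1) / 3
            else:
                out[3 * i + g] = df(step)
    return out


def central_fd_jacobian(func, positions_objs, step=1e-4, richardson=True):
    """Finite-difference Jacobian of a vector function of core positions."""
    n3 = 3 * len(positions_objs)
    cols = []
    for obj in positions_objs:
        for g in range(3):
            orig = obj.position[g]

            def df(h):
                obj.position[g] = orig + h
                vp = np.asarray(func())
                obj.position[g] = orig - h
                vm = np.asarray(func())
                obj.position[g] = orig
                return (vp - vm) / (2 * h)

            if richardson:
                d1, d2 = df(step), df(step / 2)
                cols.append((4 * d2 - d1) / 3)
            else:
                cols.append(df(step))
    return np.column_stack(cols)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
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
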