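"""Deterministic miniature states for tests and examples.

A :class:`FixtureSpec` describes a small lattice (21 x 21 by default) with
exact cell placements, vessel sites, and analytic field shapes (constants,
linear ramps, or a point mass), so unit tests can assert against hand
computations instead of full simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import CellPopulation, FieldState, PROLIFERATIVE, VesselSet

__all__ = ["FixtureSpec", "make_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a miniature state.

    ``cells`` is a sequence of (row, col, state, age_hours); ``vessel_sites``
    a sequence of (row, col).  Each field spec is either a scalar (constant
    lattice), a tuple ``("ramp", axis, lo, hi)`` for a linear ramp along rows
    (axis 0) or columns (axis 1), or ``("point", row, col, value)`` for a
    single point mass on a zero background.
    """

    grid_n: int = 21
    cells: tuple = ()
    vessel_sites: tuple = ()
    f: object = 1.0
    m: object = 0.0
    c: object = 1.0
    a: object = 0.0
    seed: int = 0


def _build_field(spec, g: int) -> np.ndarray:
    if np.isscalar(spec):
        return np.full((g, g), float(spec))
    kind = spec[0]
    if kind == "ramp":
        _, axis, lo, hi = spec
        line = np.linspace(lo, hi, g)
        return np.tile(line, (g, 1)) if axis == 1 else np.tile(line[:, None], (1, g))
    if kind == "point":
        _, r, c, v = spec
        arr = np.zeros((g, g))
        arr[r, c] = v
        return arr
    raise ValueError(f"unknown field spec {spec!r}")


def make_fixture(spec: FixtureSpec):
    """Build (FieldState, CellPopulation, VesselSet) from a spec.

    Site collisions and off-grid placements raise.  The same spec always
    yields identical states.
    """
    g = spec.grid_n
    fields = FieldState(
        f=_build_field(spec.f, g),
        m=_build_field(spec.m, g),
        c=_build_field(spec.c, g),
        a=_build_field(spec.a, g),
    )
    cells = CellPopulation(g)
    for entry in spec.cells:
        if len(entry) == 2:
            r, c = entry
            state, age = PROLIFERATIVE, 0.0
        else:
            r, c, state, age = entry
        cells.add_cell(int(r), int(c), int(state), float(age))
    vessels = VesselSet.empty(g)
    for r, c in spec.vessel_sites:
        if not (0 <= r < g and 0 <= c < g):
            raise ValueError(f"vessel site ({r}, {c}) off-grid")
        vessels.mask[r, c] = True
    return fields, cells, vessels
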