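"""In-memory state of a coupled simulation: continuum lattices, the discrete
cell population with its occupancy index, and the vessel-point set.

Cell states are encoded as small integers so the population can be stored in
flat numpy arrays and shared with the compiled cell-phase kernel:

* ``PROLIFERATIVE`` (0) — alive, free to move and divide;
* ``QUIESCENT`` (1) — alive but boxed in, stationary;
* ``DEAD`` (2) — necrotic, permanently occupies its site.

The occupancy grid stores ``-1`` for an empty site, otherwise the cell index,
and the parallel state grid stores ``EMPTY``/state codes for fast mask
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PROLIFERATIVE",
    "QUIESCENT",
    "DEAD",
    "EMPTY",
    "STATE_NAMES",
    "FieldState",
    "CellPopulation",
    "VesselSet",
    "OccupancyMasks",
]

PROLIFERATIVE = 0
QUIESCENT = 1
DEAD = 2
EMPTY = -1

STATE_NAMES = {PROLIFERATIVE: "proliferative", QUIESCENT: "quiescent", DEAD: "dead"}


@dataclass
class FieldState:
    """The four continuum lattices: ECM ``f``, MDE ``m``, oxygen ``c``, TAF ``a``."""

    f: np.ndarray
    m: np.ndarray
    c: np.ndarray
    a: np.ndarray

    def validate(self) -> None:
        shapes = {arr.shape for arr in (self.f, self.m, self.c, self.a)}
        if len(shapes) != 1:
            raise ValueError(f"field shapes differ: {shapes}")
        for name in "fmca":
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"field {name} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"field {name} contains negative values")

    def copy(self) -> "FieldState":
        return FieldState(self.f.copy(), self.m.copy(), self.c.copy(), self.a.copy())


class CellPopulation:
    """Discrete tumor cells stored as parallel arrays plus an occupancy index.

    Arrays are over-allocated to the lattice capacity (one cell per site is
    the hard maximum) so the compiled kernel can append daughters in place.
    """

    def __init__(self, grid_n: int):
        self.grid_n = grid_n
        cap = grid_n * grid_n
        self.rows = np.zeros(cap, dtype=np.int32)
        self.cols = np.zeros(cap, dtype=np.int32)
        self.states = np.zeros(cap, dtype=np.int8)
        self.ages = np.zeros(cap, dtype=np.float64)  # hours
        self.n_cells = 0
        # occupancy: cell index per site, -1 empty
        self.occupancy = np.full((grid_n, grid_n), -1, dtype=np.int32)
        # per-site state code, EMPTY where no cell
        self.state_grid = np.full((grid_n, grid_n), EMPTY, dtype=np.int8)

    # -- construction ----------------------------------------------------

    def add_cell(self, row: int, col: int, state: int = PROLIFERATIVE,
                 age: float = 0.0) -> int:
        if not (0 <= row < self.grid_n and 0 <= col < self.grid_n):
            raise ValueError(f"site ({row}, {col}) off-grid")
        if self.occupancy[row, col] != -1:
            raise ValueError(f"site ({row}, {col}) already occupied")
        if age < 0:
            raise ValueError("age must be >= 0")
        idx = self.n_cells
        self.rows[idx] = row
        self.cols[idx] = col
        self.states[idx] = state
        self.ages[idx] = age
        self.occupancy[row, col] = idx
        self.state_grid[row, col] = state
        self.n_cells += 1
        return idx

    # -- queries ---------------------------------------------------------

    def counts(self) -> dict:
        s = self.states[: self.n_cells]
        return {
            "proliferative": int(np.sum(s == PROLIFERATIVE)),
            "quiescent": int(np.sum(s == QUIESCENT)),
            "dead": int(np.sum(s == DEAD)),
        }

    def sites(self) -> np.ndarray:
        """(n_cells, 2) array of (row, col) sites."""
        return np.stack(
            [self.rows[: self.n_cells], self.cols[: self.n_cells]], axis=1
        )

    def validate(self) -> None:
        """Full audit: occupancy index and cell list must agree exactly."""
        n = self.n_cells
        occ = np.full((self.grid_n, self.grid_n), -1, dtype=np.int32)
        sg = np.full((self.grid_n, self.grid_n), EMPTY, dtype=np.int8)
        for i in range(n):
            r, c = self.rows[i], self.cols[i]
            if occ[r, c] != -1:
                raise ValueError(f"two cells share site ({r}, {c})")
            occ[r, c] = i
            sg[r, c] = self.states[i]
        if not np.array_equal(occ, self.occupancy):
            raise ValueError("occupancy index disagrees with cell list")
        if not np.array_equal(sg, self.state_grid):
            raise ValueError("state grid disagrees with cell list")
        if np.any(self.ages[:n] < 0):
            raise ValueError("negative cell age")

    def copy(self) -> "CellPopulation":
        other = CellPopulation(self.grid_n)
        other.rows = self.rows.copy()
        other.cols = self.cols.copy()
        other.states = self.states.copy()
        other.ages = self.ages.copy()
        other.n_cells = self.n_cells
        other.occupancy = self.occupancy.copy()
        other.state_grid = self.state_grid.copy()
        return other


@dataclass
class VesselSet:
    """Current vascular points as a boolean lattice mask.

    Vessel points are capillary cross-sections: they may coexist with cells
    and act as Dirichlet oxygen sources (c pinned to 1) while they exist.
    """

    mask: np.ndarray
    last_update_hours: float = 0.0

    @classmethod
    def empty(cls, grid_n: int) -> "VesselSet":
        return cls(mask=np.zeros((grid_n, grid_n), dtype=bool), last_update_hours=0.0)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def sites(self) -> np.ndarray:
        """(k, 2) array of vessel (row, col) sites."""
        return np.argwhere(self.mask)

    def copy(self) -> "VesselSet":
        return VesselSet(self.mask.copy(), self.last_update_hours)


@dataclass
class OccupancyMasks:
    """Boolean lattices derived from the cell population for the field steps.

    ``live_mask`` marks sites with a proliferative or quiescent cell (the
    discrete realisation of the cell density in the production/uptake terms);
    ``hypoxic_live_mask`` additionally requires local oxygen at or below the
    TAF-secretion threshold; ``tumor_interior_mask`` marks sites within the
    current tumor radius (oxygen diffuses more slowly there).
    """

    live_mask: np.ndarray
    hypoxic_live_mask: np.ndarray
    tumor_interior_mask: np.ndarray
    proliferative_mask: np.ndarray = None
    quiescent_mask: np.ndarray = None

    def validate(self) -> None:
        if self.live_mask.shape != self.hypoxic_live_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.hypoxic_live_mask & ~self.live_mask):
            raise ValueError("hypoxic_live_mask must be a subset of live_mask")


def init_state(config, rng: np.random.Generator):
    """Build the initial simulation state.

    ECM is i.i.d. Uniform(0,1) per site, MDE and TAF are zero, oxygen is 1
    everywhere, and there are no vessel points.  ``n_init_cells`` (a perfect
    square) proliferative cells are placed as a centered square block with
    i.i.d. Uniform(0, age_max_hours) ages.  RNG draw order is fixed: the ECM
    lattice first, then the ages.

    Returns ``(FieldState, CellPopulation, VesselSet)``.
    """
    g = config.grid_n
    f = rng.random((g, g))
    m = np.zeros((g, g))
    c = np.ones((g, g))
    a = np.zeros((g, g))
    fields = FieldState(f=f, m=m, c=c, a=a)

    k = int(round(np.sqrt(config.n_init_cells)))
    if k * k != config.n_init_cells:
        raise ValueError(
            f"n_init_cells = {config.n_init_cells} is not a perfect square; "
            "the centered block layout requires one"
        )
    if k > g:
        raise ValueError("initial block larger than the lattice")
    ages = rng.uniform(0.0, config.age_max_hours, size=config.n_init_cells)
    cells = CellPopulation(g)
    start = (g - k) // 2
    idx = 0
    for i in range(start, start + k):
        for j in range(start, start + k):
            cells.add_cell(i, j, PROLIFERATIVE, age=float(ages[idx]))
            idx += 1

    vessels = VesselSet.empty(g)
    return fields, cells, vessels


def compute_masks(cells: CellPopulation, c: np.ndarray, c_hypoxia: float,
                  tumor_interior_mask: np.ndarray) -> OccupancyMasks:
    """Build the field-step masks from the current population and oxygen."""
    sg = cells.state_grid
    prolif = sg == PROLIFERATIVE
    quiesc = sg == QUIESCENT
    live = prolif | quiesc
    return OccupancyMasks(
        live_mask=live,
        hypoxic_live_mask=live & (c <= c_hypoxia),
        tumor_interior_mask=tumor_interior_mask,
        proliferative_mask=prolif,
        quiescent_mask=quiesc,
    )
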