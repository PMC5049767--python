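"""Discrete tumor-cell dynamics: biased random-walk movement, the
oxygen/space state machine, and mitosis.

Movement probabilities come from discretising the cell-density equation
(random motility + haptotaxis up the ECM gradient): with k = dt/h^2 and
central differences of the ECM field f,

    p_right = k * [dn + (rho/4) * (f_E - f_W)]
    p_left  = k * [dn - (rho/4) * (f_E - f_W)]

(and analogously up/down with the row axis), rho = (3c + 0.7) * rho_std at
the cell's site, p_stay the remainder.  Negative coefficients are clamped to
zero and the five values renormalised to sum to one.

State machine, applied to every live cell each step:

* oxygen below ``c_death`` -> dead (irreversible; the corpse keeps its site);
* otherwise no empty von-Neumann neighbor -> quiescent;
* otherwise -> proliferative (quiescent cells reactivate when space frees).

Orthogonally to that classification, completing a division requires oxygen
above the hypoxia threshold (0.4 by default): under hypoxia the division
attempt aborts and the cell cycle restarts (the ``hypoxic_arrest`` switch,
on by default).  Hypoxic proliferative cells still move, consume oxygen and
secrete TAF.

Only proliferative cells move and divide.  A proliferative cell whose age
has reached the mitosis threshold attempts one division per cycle; the
default placement rule draws one of the four von-Neumann directions at
random and fails when the target is occupied (graded contact inhibition —
see :func:`attempt_mitosis` for the alternative ``any_empty`` mode).

The functions here are the scalar, per-cell reference semantics; the engine
executes the same rules through a compiled kernel (see ``_kernel``), and the
test suite cross-checks the two step-for-step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .fields import oxygen_scaled
from .state import CellPopulation, DEAD, EMPTY, PROLIFERATIVE, QUIESCENT

__all__ = [
    "MoveProbabilities",
    "movement_probabilities",
    "attempt_move",
    "update_cell_state",
    "attempt_mitosis",
    "cell_phase_reference",
    "NEIGHBOR_OFFSETS",
]

#: von-Neumann neighbor order used everywhere (up, down, left, right).
NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class MoveProbabilities:
    """One cell's five movement outcomes for one step (sums to 1)."""

    p_stay: float
    p_left: float
    p_right: float
    p_up: float
    p_down: float

    def as_tuple(self):
        return (self.p_stay, self.p_left, self.p_right, self.p_up, self.p_down)

    def validate(self) -> None:
        vals = self.as_tuple()
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError(f"probabilities outside [0, 1]: {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"probabilities do not sum to 1: {vals}")


def _clamped_diff(f: np.ndarray, i: int, j: int, axis: int) -> float:
    """Central difference of f along an axis, clamped at the boundary ring."""
    n_rows, n_cols = f.shape
    if axis == 1:  # columns: east - west
        e = f[i, j + 1] if j + 1 < n_cols else f[i, j]
        w = f[i, j - 1] if j - 1 >= 0 else f[i, j]
    else:  # rows: "down" (i+1) - "up" (i-1)
        e = f[i + 1, j] if i + 1 < n_rows else f[i, j]
        w = f[i - 1, j] if i - 1 >= 0 else f[i, j]
    return e - w


def movement_probabilities(site, f: np.ndarray, c_local: float,
                           config: SimulationConfig) -> MoveProbabilities:
    """Movement distribution for one cell from the local ECM gradient.

    Moves up the ECM gradient are favored (haptotaxis toward higher f).
    Boundary sites use clamped differences; moves off-grid are cancelled
    later by :func:`attempt_move`.
    """
    k = config.dt / (config.h * config.h)
    if k * config.dn >= 0.25:
        raise ValueError(
            f"dt too large: k*dn = {k * config.dn:.3g} >= 0.25, "
            "movement probabilities ill-posed"
        )
    i, j = site
    rho = float(oxygen_scaled(c_local, config.rho_std))
    dfx = _clamped_diff(f, i, j, axis=1)  # f_E - f_W
    dfy = _clamped_diff(f, i, j, axis=0)  # f_S - f_N (row axis)
    p_right = k * (config.dn + 0.25 * rho * dfx)
    p_left = k * (config.dn - 0.25 * rho * dfx)
    p_down = k * (config.dn + 0.25 * rho * dfy)
    p_up = k * (config.dn - 0.25 * rho * dfy)
    p_left, p_right, p_up, p_down = (max(0.0, v) for v in
                                     (p_left, p_right, p_up, p_down))
    s = p_left + p_right + p_up + p_down
    if s > 1.0:
        p_left, p_right, p_up, p_down = (v / s for v in
                                         (p_left, p_right, p_up, p_down))
        p_stay = 0.0
    else:
        p_stay = 1.0 - s
    return MoveProbabilities(p_stay, p_left, p_right, p_up, p_down)


def _draw(u, rng):
    if u is not None:
        return float(u)
    return float(rng.random())


def attempt_move(cells: CellPopulation, idx: int, probs: MoveProbabilities,
                 rng=None, u: float = None,
                 adhesion_enabled: bool = False) -> tuple:
    """Sample one of the five outcomes and apply it.

    A move into an occupied or off-grid site is cancelled (the cell stays).
    With adhesion on, a move is accepted only if the destination would retain
    at least one live neighbor after the cell vacates its origin.  Returns
    the cell's (row, col) after the step.
    """
    if cells.states[idx] != PROLIFERATIVE:
        raise ValueError("only proliferative cells move")
    uu = _draw(u, rng)
    i, j = int(cells.rows[idx]), int(cells.cols[idx])
    # cumulative order: stay, left, right, up, down
    edges = np.cumsum(probs.as_tuple())
    choice = int(np.searchsorted(edges, uu, side="right"))
    choice = min(choice, 4)
    if choice == 0:
        return (i, j)
    di, dj = ((0, -1), (0, 1), (-1, 0), (1, 0))[choice - 1]
    ni, nj = i + di, j + dj
    n = cells.grid_n
    if not (0 <= ni < n and 0 <= nj < n):
        return (i, j)
    if cells.occupancy[ni, nj] != -1:
        return (i, j)
    if adhesion_enabled and not _has_live_neighbor(cells, ni, nj, exclude=(i, j)):
        return (i, j)
    cells.occupancy[i, j] = -1
    cells.state_grid[i, j] = EMPTY
    cells.occupancy[ni, nj] = idx
    cells.state_grid[ni, nj] = cells.states[idx]
    cells.rows[idx] = ni
    cells.cols[idx] = nj
    return (ni, nj)


def _has_live_neighbor(cells: CellPopulation, i: int, j: int,
                       exclude=None) -> bool:
    n = cells.grid_n
    for di, dj in NEIGHBOR_OFFSETS:
        ni, nj = i + di, j + dj
        if not (0 <= ni < n and 0 <= nj < n):
            continue
        if exclude is not None and (ni, nj) == exclude:
            continue
        if cells.state_grid[ni, nj] in (PROLIFERATIVE, QUIESCENT):
            return True
    return False


def _empty_neighbors(cells: CellPopulation, i: int, j: int) -> list:
    n = cells.grid_n
    out = []
    for di, dj in NEIGHBOR_OFFSETS:
        ni, nj = i + di, j + dj
        if 0 <= ni < n and 0 <= nj < n and cells.occupancy[ni, nj] == -1:
            out.append((ni, nj))
    return out


def update_cell_state(cells: CellPopulation, idx: int, c_local: float,
                      config: SimulationConfig) -> int:
    """Apply the oxygen/space state machine to one live cell; returns the state."""
    state = int(cells.states[idx])
    if state == DEAD:
        return DEAD
    i, j = int(cells.rows[idx]), int(cells.cols[idx])
    if c_local < config.c_death:
        new = DEAD
    elif not _empty_neighbors(cells, i, j):
        new = QUIESCENT
    else:
        new = PROLIFERATIVE
    cells.states[idx] = new
    cells.state_grid[i, j] = new
    return new


def attempt_mitosis(cells: CellPopulation, idx: int, rng=None, u: float = None,
                    config: SimulationConfig = None, c_local: float = None):
    """One division attempt for a proliferative cell whose age has reached
    the mitosis threshold.

    In the default ``random_direction`` mode the division axis is drawn
    uniformly among the four von-Neumann directions; if the target site is
    occupied or off-grid the attempt fails, and the cell-cycle clock resets
    either way.  Contact inhibition is therefore graded: a cell with one
    free neighbor succeeds in only a quarter of its cycles, which slows rim
    expansion to the sub-site-per-cycle regime a compact tumor exhibits.

    In ``any_empty`` mode the daughter is instead placed uniformly among the
    currently empty neighbors, so any cell with space divides every cycle
    (maximal growth; useful as an upper-bound comparison).

    With the default ``hypoxic_arrest``, completing mitosis additionally
    requires oxygen above the hypoxia threshold: under hypoxia the division
    aborts at this checkpoint and the cycle restarts (age resets), so
    late-stage growth is limited by the vascular oxygen supply rather than
    by space alone.  Movement is unaffected.

    The daughter is proliferative with age 0.  Returns the daughter's index,
    or None when no daughter was placed.
    """
    if cells.states[idx] != PROLIFERATIVE:
        return None
    if cells.ages[idx] < config.age_max_hours:
        return None
    if config.hypoxic_arrest and c_local is not None \
            and c_local <= config.c_hypoxia:
        cells.ages[idx] = 0.0  # checkpoint abort consumes the cycle
        return None
    i, j = int(cells.rows[idx]), int(cells.cols[idx])
    empties = _empty_neighbors(cells, i, j)
    if not empties:
        return None
    uu = _draw(u, rng)
    if config.mitosis_mode == "random_direction":
        t = min(int(uu * 4.0), 3)
        ni, nj = i + NEIGHBOR_OFFSETS[t][0], j + NEIGHBOR_OFFSETS[t][1]
        n = cells.grid_n
        cells.ages[idx] = 0.0  # the cycle is consumed even on failure
        if not (0 <= ni < n and 0 <= nj < n) or cells.occupancy[ni, nj] != -1:
            return None
        return cells.add_cell(ni, nj, PROLIFERATIVE, age=0.0)
    pick = min(int(uu * len(empties)), len(empties) - 1)
    ni, nj = empties[pick]
    daughter = cells.add_cell(ni, nj, PROLIFERATIVE, age=0.0)
    cells.ages[idx] = 0.0
    return daughter


def cell_phase_reference(cells: CellPopulation, f: np.ndarray, c: np.ndarray,
                         config: SimulationConfig, perm: np.ndarray,
                         u_mit: np.ndarray, u_move: np.ndarray) -> None:
    """Pure-Python cell phase over one step, mirroring the compiled kernel.

    Cells existing at step start are processed in the order given by
    ``perm``; per slot k the random numbers ``u_mit[k]`` and ``u_move[k]``
    drive the mitosis placement and movement draw.  Per cell: advance age by
    dt*tau hours, update state, attempt mitosis, attempt movement.
    """
    dt_h = config.dt * config.tau_hours
    for k in range(len(perm)):
        idx = int(perm[k])
        if cells.states[idx] == DEAD:
            continue
        cells.ages[idx] += dt_h
        i, j = int(cells.rows[idx]), int(cells.cols[idx])
        state = update_cell_state(cells, idx, float(c[i, j]), config)
        if state != PROLIFERATIVE:
            continue
        attempt_mitosis(cells, idx, u=u_mit[k], config=config,
                        c_local=float(c[i, j]))
        probs = movement_probabilities(
            (int(cells.rows[idx]), int(cells.cols[idx])), f,
            float(c[int(cells.rows[idx]), int(cells.cols[idx])]), config)
        attempt_move(cells, idx, probs, u=u_move[k],
                     adhesion_enabled=config.adhesion_enabled)
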