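"""Compiled per-step cell phase.

This is the production path for the discrete cell dynamics: the same rules
as :mod:`tumorangio.cells` (age advance, oxygen/space state machine, mitosis,
biased random-walk movement), written as a single numba kernel over the flat
population arrays.  All randomness is consumed from pre-drawn arrays
(permutation and per-slot uniforms) generated by the run's single RNG
stream, so the kernel itself is deterministic and the reference Python path
and this kernel produce bit-identical trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PROLIFERATIVE = 0
QUIESCENT = 1
DEAD = 2
EMPTY = -1


@njit(cache=True)
def _count_empty_neighbors(occ, i, j, n, out_rows, out_cols):
    """Empty von-Neumann neighbors of (i, j) in (up, down, left, right) order."""
    k = 0
    if i - 1 >= 0 and occ[i - 1, j] == -1:
        out_rows[k] = i - 1
        out_cols[k] = j
        k += 1
    if i + 1 < n and occ[i + 1, j] == -1:
        out_rows[k] = i + 1
        out_cols[k] = j
        k += 1
    if j - 1 >= 0 and occ[i, j - 1] == -1:
        out_rows[k] = i
        out_cols[k] = j - 1
        k += 1
    if j + 1 < n and occ[i, j + 1] == -1:
        out_rows[k] = i
        out_cols[k] = j + 1
        k += 1
    return k


@njit(cache=True)
def _has_live_neighbor(state_grid, i, j, n, ex_i, ex_j):
    for t in range(4):
        if t == 0:
            ni, nj = i - 1, j
        elif t == 1:
            ni, nj = i + 1, j
        elif t == 2:
            ni, nj = i, j - 1
        else:
            ni, nj = i, j + 1
        if ni < 0 or ni >= n or nj < 0 or nj >= n:
            continue
        if ni == ex_i and nj == ex_j:
            continue
        s = state_grid[ni, nj]
        if s == PROLIFERATIVE or s == QUIESCENT:
            return True
    return False


@njit(cache=True)
def cell_phase_kernel(rows, cols, states, ages, n_cells, occ, state_grid,
                      f, c, perm, u_mit, u_move,
                      dt, h, tau_hours, dn, rho_std, c_death, age_max_hours,
                      adhesion_enabled, mitosis_random_direction,
                      hypoxic_arrest, c_hypoxia):
    """Advance every cell existing at step start; returns the new cell count.

    Cells are processed in the order given by ``perm``; daughters appended
    during the step are processed from the next step on.
    """
    n = occ.shape[0]
    k_diff = dt / (h * h)
    dt_h = dt * tau_hours
    nb_r = np.empty(4, dtype=np.int64)
    nb_c = np.empty(4, dtype=np.int64)
    for slot in range(perm.shape[0]):
        idx = perm[slot]
        if states[idx] == DEAD:
            continue
        ages[idx] += dt_h
        i = rows[idx]
        j = cols[idx]
        # --- state machine ---
        if c[i, j] < c_death:
            states[idx] = DEAD
            state_grid[i, j] = DEAD
            continue
        n_empty = _count_empty_neighbors(occ, i, j, n, nb_r, nb_c)
        if n_empty == 0:
            states[idx] = QUIESCENT
            state_grid[i, j] = QUIESCENT
            continue
        states[idx] = PROLIFERATIVE
        state_grid[i, j] = PROLIFERATIVE
        # --- mitosis ---
        if ages[idx] >= age_max_hours:
            # oxygen checkpoint: under hypoxia the division aborts and the
            # cycle restarts; movement below is unaffected
            place = not (hypoxic_arrest and c[i, j] <= c_hypoxia)
            di, dj = i, j
            if place and mitosis_random_direction:
                # one random direction among the four; an occupied or
                # off-grid target aborts this division attempt, and the
                # cycle is consumed either way
                t = int(u_mit[slot] * 4.0)
                if t > 3:
                    t = 3
                if t == 0:
                    di, dj = i - 1, j
                elif t == 1:
                    di, dj = i + 1, j
                elif t == 2:
                    di, dj = i, j - 1
                else:
                    di, dj = i, j + 1
                if di < 0 or di >= n or dj < 0 or dj >= n or occ[di, dj] != -1:
                    place = False
            elif place:
                pick = int(u_mit[slot] * n_empty)
                if pick > n_empty - 1:
                    pick = n_empty - 1
                di = nb_r[pick]
                dj = nb_c[pick]
            if place:
                d_idx = n_cells
                rows[d_idx] = di
                cols[d_idx] = dj
                states[d_idx] = PROLIFERATIVE
                ages[d_idx] = 0.0
                occ[di, dj] = d_idx
                state_grid[di, dj] = PROLIFERATIVE
                n_cells += 1
            ages[idx] = 0.0
        # --- movement ---
        rho = (3.0 * c[i, j] + 0.7) * rho_std
        fe = f[i, j + 1] if j + 1 < n else f[i, j]
        fw = f[i, j - 1] if j - 1 >= 0 else f[i, j]
        fs = f[i + 1, j] if i + 1 < n else f[i, j]
        fn_ = f[i - 1, j] if i - 1 >= 0 else f[i, j]
        dfx = fe - fw
        dfy = fs - fn_
        p_right = k_diff * (dn + 0.25 * rho * dfx)
        p_left = k_diff * (dn - 0.25 * rho * dfx)
        p_down = k_diff * (dn + 0.25 * rho * dfy)
        p_up = k_diff * (dn - 0.25 * rho * dfy)
        p_left = max(0.0, p_left)
        p_right = max(0.0, p_right)
        p_up = max(0.0, p_up)
        p_down = max(0.0, p_down)
        s = p_left + p_right + p_up + p_down
        if s > 1.0:
            p_left = p_left / s
            p_right = p_right / s
            p_up = p_up / s
            p_down = p_down / s
            p_stay = 0.0
        else:
            p_stay = 1.0 - s
        u = u_move[slot]
        # cumulative order: stay, left, right, up, down
        cum = p_stay
        if u < cum:
            continue
        cum += p_left
        if u < cum:
            ni, nj = i, j - 1
        else:
            cum += p_right
            if u < cum:
                ni, nj = i, j + 1
            else:
                cum += p_up
                if u < cum:
                    ni, nj = i - 1, j
                else:
                    ni, nj = i + 1, j
        if ni < 0 or ni >= n or nj < 0 or nj >= n:
            continue
        if occ[ni, nj] != -1:
            continue
        if adhesion_enabled and not _has_live_neighbor(state_grid, ni, nj, n, i, j):
            continue
        occ[i, j] = -1
        state_grid[i, j] = EMPTY
        occ[ni, nj] = idx
        state_grid[ni, nj] = PROLIFERATIVE
        rows[idx] = ni
        cols[idx] = nj
    return n_cells
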