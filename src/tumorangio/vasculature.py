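"""Tumor geometry and the stochastic vascular-point generator.

Vessels are not tracked as sprouting endothelial structures; the model keeps
only a set of lattice "vessel points" (capillary cross-sections) that act as
Dirichlet oxygen sources.  At every refresh (every 2 simulated hours by
default) each lattice site independently receives a vessel point with
probability

    P_b = p_c                    if r/r0 <= 0.5   (inner tumor region)
        = min(1, p * a(site))    otherwise        (TAF-proportional)

where r is the site's distance from the tumor center and r0 the current
tumor radius.  With the default p_c = 0 the inner half of the tumor can
never receive a vessel, which produces the avascular necrotic core.  The
default mode discards the previous vessel set at each refresh (capillaries
inside a tumor are transient); ``accumulate`` keeps old points and only adds
new ones, for comparison.

The tumor is summarised by its centroid (over all cells, live and dead) and
a robust radius r0: the 95th percentile of live-cell distances from the
centroid, floored at one lattice spacing.  Distances are Euclidean in the
continuous (non-dimensional) coordinates of lattice sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .state import CellPopulation, DEAD, VesselSet

__all__ = [
    "TumorGeometry",
    "tumor_geometry",
    "vessel_probability",
    "vessel_probability_grid",
    "update_vessels",
    "vessel_refresh_due",
    "tumor_interior_mask",
]


@dataclass(frozen=True)
class TumorGeometry:
    """Tumor centroid (continuous lattice coordinates) and radius r0 (non-dim)."""

    center_row: float
    center_col: float
    r0: float

    def validate(self, grid_n: int) -> None:
        if self.r0 < 0:
            raise ValueError("r0 must be >= 0")
        if not (0 <= self.center_row <= grid_n - 1
                and 0 <= self.center_col <= grid_n - 1):
            raise ValueError("tumor center outside the domain")


def tumor_geometry(cells: CellPopulation, h: float) -> TumorGeometry:
    """Centroid of all cells; r0 = 95th percentile of live-cell distances.

    The percentile makes r0 robust to stray walkers ahead of the tumor rim;
    the floor of one lattice spacing keeps r0 positive for a point tumor.
    """
    n = cells.n_cells
    if n == 0:
        raise ValueError("tumor geometry undefined for an empty population")
    rows = cells.rows[:n].astype(np.float64)
    cols = cells.cols[:n].astype(np.float64)
    cr = rows.mean()
    cc = cols.mean()
    live = cells.states[:n] != DEAD
    if live.any():
        d = np.hypot(rows[live] - cr, cols[live] - cc) * h
        r0 = float(np.percentile(d, 95.0))
    else:
        d = np.hypot(rows - cr, cols - cc) * h
        r0 = float(np.percentile(d, 95.0))
    return TumorGeometry(center_row=cr, center_col=cc, r0=max(r0, h))


def _radius_grid(grid_n: int, h: float, geom: TumorGeometry) -> np.ndarray:
    """Distance of every lattice site from the tumor center, non-dim units."""
    ii = np.arange(grid_n, dtype=np.float64)
    rr = (ii[:, None] - geom.center_row) * h
    cc = (ii[None, :] - geom.center_col) * h
    return np.hypot(rr, cc)


def vessel_probability(site, a_local: float, geom: TumorGeometry,
                       config: SimulationConfig) -> float:
    """Per-site Bernoulli probability of carrying a vessel point."""
    if a_local < 0:
        raise ValueError("TAF concentration must be >= 0")
    i, j = site
    r = np.hypot((i - geom.center_row) * config.h,
                 (j - geom.center_col) * config.h)
    if r / geom.r0 <= 0.5:
        return float(config.p_c)
    return float(min(1.0, config.p * a_local))


def vessel_probability_grid(a: np.ndarray, geom: TumorGeometry,
                            config: SimulationConfig) -> np.ndarray:
    """Vectorised :func:`vessel_probability` over the whole lattice."""
    r = _radius_grid(a.shape[0], config.h, geom)
    outer = np.minimum(1.0, config.p * a)
    return np.where(r / geom.r0 <= 0.5, config.p_c, outer)


def update_vessels(a: np.ndarray, vessels: VesselSet, geom: TumorGeometry,
                   rng: np.random.Generator, config: SimulationConfig,
                   now_hours: float) -> VesselSet:
    """One scheduled vessel refresh.

    ``resample`` (default): discard all existing points, then draw one
    Bernoulli trial per lattice site.  ``accumulate``: keep existing points
    and add new draws only at currently vessel-free sites.  One uniform is
    consumed per lattice site in either mode, so the RNG stream advances
    identically.
    """
    pb = vessel_probability_grid(a, geom, config)
    draws = rng.random(pb.shape) < pb
    if config.vessel_mode == "resample":
        mask = draws
    else:  # accumulate
        mask = vessels.mask | draws
    return VesselSet(mask=mask, last_update_hours=now_hours)


def vessel_refresh_due(step: int, dt: float, tau_hours: float,
                       vessel_update_hours: float,
                       last_update_hours: float) -> bool:
    """True when the end-of-step clock has advanced a full refresh interval.

    With dt = 0.002 and tau = 16 h one interval of 2 h is 62.5 steps, so
    successive refreshes alternate between 62 and 63 steps via the time
    accumulator (first refresh at step 63, t = 2.016 h).
    """
    if step <= 0:
        return False
    now = step * dt * tau_hours
    return now - last_update_hours >= vessel_update_hours


def tumor_interior_mask(grid_n: int, h: float, geom: TumorGeometry) -> np.ndarray:
    """Sites within distance r0 of the tumor center (slow-oxygen region)."""
    return _radius_grid(grid_n, h, geom) <= geom.r0
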