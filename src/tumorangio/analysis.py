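"""Derived outputs: cell/vessel counts, radial density profiles, replicate
statistics and parameter-sensitivity sweeps.

The radial profile bins every lattice site by its normalised distance r/r0
from the tumor center (bin width 0.05, covering [0, 1.25] plus an overflow
bin) and reports, per annulus, the fraction of sites occupied by each cell
state and by vessel points.  Defining vessel "density" as an occupied-site
fraction makes it dimensionless and bounded by 1, which is the natural scale
for a percentage plateau/peak readout.

Replicate statistics are the mean and sample (n-1) standard deviation over
independent full runs of the counts at a stated hour: surviving
(proliferative + quiescent), proliferative, quiescent and dead cells, and
capillary (vessel) points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .engine import RunResult, SimulationState, run
from .state import DEAD, PROLIFERATIVE, QUIESCENT
from .vasculature import TumorGeometry, tumor_geometry

__all__ = [
    "CountSummary",
    "RadialProfile",
    "count_cells",
    "radial_profile",
    "replicate_summary",
    "sensitivity_sweep",
    "REPLICATE_QUANTITIES",
]

REPLICATE_QUANTITIES = ("survival", "proliferative", "quiescent", "dead",
                        "capillary")


@dataclass(frozen=True)
class CountSummary:
    proliferative: int
    quiescent: int
    dead: int
    vessels: int

    @property
    def survival(self) -> int:
        return self.proliferative + self.quiescent

    @property
    def total(self) -> int:
        return self.survival + self.dead


def count_cells(state: SimulationState) -> CountSummary:
    """Exact tallies by state plus the vessel-point count."""
    c = state.cells.counts()
    return CountSummary(proliferative=c["proliferative"],
                        quiescent=c["quiescent"], dead=c["dead"],
                        vessels=state.vessels.count)


@dataclass
class RadialProfile:
    """Per-annulus occupied-site fractions along r/r0.

    ``edges`` has len(bins)+1 entries; the last bin is the open-ended
    overflow (r/r0 beyond the nominal range) so that density * n_sites summed
    over bins recovers every global count exactly.
    """

    edges: np.ndarray
    n_sites: np.ndarray
    frac_proliferative: np.ndarray
    frac_quiescent: np.ndarray
    frac_dead: np.ndarray
    frac_live: np.ndarray
    frac_vessel: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        mid = 0.5 * (self.edges[:-1] + self.edges[1:])
        return mid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_over_r0_lo": self.edges[:-1],
            "r_over_r0_hi": self.edges[1:],
            "n_sites": self.n_sites,
            "proliferative": self.frac_proliferative,
            "quiescent": self.frac_quiescent,
            "dead": self.frac_dead,
            "live": self.frac_live,
            "vessel": self.frac_vessel,
        })


def radial_profile(state: SimulationState, geom: TumorGeometry = None,
                   bin_width: float = 0.05, r_max: float = 1.25,
                   h: float = None) -> RadialProfile:
    """Radial occupied-site fractions around the tumor center.

    ``geom`` defaults to a fresh estimate from the current population.  Bins
    of ``bin_width`` cover [0, r_max] in r/r0 with one trailing overflow bin.
    """
    g = state.cells.grid_n
    if h is None:
        h = 1.0 / (g - 1)
    if geom is None:
        geom = tumor_geometry(state.cells, h)
    if geom.r0 <= 0:
        raise ValueError("radial profile undefined for r0 = 0")
    ii = np.arange(g, dtype=np.float64)
    rr = np.hypot((ii[:, None] - geom.center_row) * h,
                  (ii[None, :] - geom.center_col) * h) / geom.r0
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.append(np.arange(n_bins + 1) * bin_width, np.inf)
    idx = np.minimum((rr / bin_width).astype(np.int64), n_bins)

    sg = state.cells.state_grid
    n_sites = np.bincount(idx.ravel(), minlength=n_bins + 1)

    def frac(mask):
        counts = np.bincount(idx.ravel(), weights=mask.ravel().astype(float),
                             minlength=n_bins + 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(n_sites > 0, counts / np.maximum(n_sites, 1), 0.0)
        return out

    prolif = sg == PROLIFERATIVE
    quiesc = sg == QUIESCENT
    dead = sg == DEAD
    return RadialProfile(
        edges=edges,
        n_sites=n_sites,
        frac_proliferative=frac(prolif),
        frac_quiescent=frac(quiesc),
        frac_dead=frac(dead),
        frac_live=frac(prolif | quiesc),
        frac_vessel=frac(state.vessels.mask),
    )


def _counts_row(result: RunResult, at_hours: float) -> dict:
    row = result.counts_at(at_hours)
    return {
        "survival": float(row["live_total"]),
        "proliferative": float(row["proliferative"]),
        "quiescent": float(row["quiescent"]),
        "dead": float(row["dead"]),
        "capillary": float(row["vessels"]),
    }


def replicate_summary(config: SimulationConfig, n_runs: int, seeds,
                      at_hours: float, results: list = None) -> pd.DataFrame:
    """Mean and sample SD of the counts at ``at_hours`` over replicate runs.

    ``seeds`` must provide ``n_runs`` entries (repeats are allowed and give
    degenerate zero-SD replicates).  Pre-computed ``results`` may be passed
    to summarise existing runs instead of re-running.  Returns a DataFrame
    indexed by quantity with columns mean/sd/n, plus one column per run.
    """
    if n_runs < 2:
        raise ValueError("replicate summary needs n_runs >= 2")
    seeds = list(seeds)
    if len(seeds) != n_runs:
        raise ValueError(f"need {n_runs} seeds, got {len(seeds)}")
    if results is None:
        results = [run(config, seed=s) for s in seeds]
    rows = [_counts_row(r, at_hours) for r in results]
    table = pd.DataFrame(rows, index=[f"run{k}" for k in range(n_runs)])
    table = table[list(REPLICATE_QUANTITIES)]
    out = pd.DataFrame({
        "mean": table.mean(axis=0),
        "sd": table.std(axis=0, ddof=1),
        "n": n_runs,
    })
    for k in range(n_runs):
        out[f"run{k}"] = table.iloc[k]
    return out


def sensitivity_sweep(base_config: SimulationConfig, param_name: str,
                      values, n_runs: int, seeds) -> pd.DataFrame:
    """Count trajectories under variations of a vessel-probability parameter.

    ``param_name`` must be ``p_c`` or ``p``.  Runs ``n_runs`` replicates per
    value and returns a tidy long table (param, value, seed, hours, quantity,
    count).
    """
    if param_name not in ("p_c", "p"):
        raise ValueError(f"unsupported sweep parameter {param_name!r}")
    seeds = list(seeds)
    if len(seeds) != n_runs:
        raise ValueError(f"need {n_runs} seeds, got {len(seeds)}")
    frames = []
    for v in values:
        if not np.isfinite(v):
            raise ValueError(f"non-finite sweep value {v!r}")
        cfg = base_config.replace(**{param_name: float(v)})
        for s in seeds:
            res = run(cfg, seed=s)
            long = res.timeseries.melt(id_vars="hours", var_name="quantity",
                                       value_name="count")
            long.insert(0, "param", param_name)
            long.insert(1, "value", float(v))
            long.insert(2, "seed", s)
            frames.append(long)
    return pd.concat(frames, ignore_index=True)
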