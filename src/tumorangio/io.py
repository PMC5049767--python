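"""Result serialization: CSV time series, npz snapshots, JSON metadata.

Every tabular output embeds the config hash and seed as comment header
lines, so reruns with the same pair are byte-identical and any file can be
traced back to its run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import RunResult, Snapshot

__all__ = ["save_result", "write_csv", "load_timeseries"]


def write_csv(df: pd.DataFrame, path, config_hash: str, seed) -> None:
    """CSV with provenance comment header (# config_hash=..., # seed=...)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n# seed={seed}\n")
        df.to_csv(fh, index=False)


def load_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _save_snapshot(snap: Snapshot, path) -> None:
    np.savez(
        path,
        step=snap.step,
        hours=snap.hours,
        f=snap.fields.f,
        m=snap.fields.m,
        c=snap.fields.c,
        a=snap.fields.a,
        cell_sites=snap.cell_sites,
        cell_states=snap.cell_states,
        cell_ages=snap.cell_ages,
        vessel_sites=snap.vessel_sites,
    )


def save_result(result: RunResult, outdir) -> Path:
    """Write time series, snapshots and a JSON metadata sidecar to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_csv(result.timeseries, outdir / "timeseries.csv",
              result.config_hash, result.seed)
    for snap in result.snapshots:
        _save_snapshot(snap, outdir / f"snapshot_{snap.step:06d}.npz")
    meta = {
        "config_hash": result.config_hash,
        "seed": int(result.seed),
        "aborted": result.aborted,
        "abort_reason": result.abort_reason,
        "elapsed_seconds": round(result.elapsed_seconds, 3),
        "n_snapshots": len(result.snapshots),
        "config": result.config.to_dict(),
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return outdir
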