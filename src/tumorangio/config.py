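"""Simulation configuration: every model constant, threshold and grid/timing
setting in one validated record.

All parameters are non-dimensional unless a unit is stated.  The reference
scales are a domain length ``L`` = 1 cm and a time scale ``tau`` = 16 h (one
average cell cycle); one time unit therefore corresponds to 16 simulated
hours and the unit square maps onto a 1 cm x 1 cm tissue patch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "default_config",
    "load_config",
    "save_config",
    "config_hash",
]

#: Stability bound for the explicit diffusion step, D*dt/h^2 <= CFL_LIMIT.
CFL_LIMIT = 0.25

_VESSEL_MODES = ("resample", "accumulate")
_MITOSIS_MODES = ("random_direction", "any_empty")


class ConfigError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameter set for one simulation run.

    Defaults are the baseline parameterisation of the model: a 201 x 201
    lattice on the unit square, explicit time step ``dt`` = 0.002, and the
    standard non-dimensional rate constants for ECM degradation, MDE and TAF
    kinetics, oxygen transport, and vessel-point generation.
    """

    # lattice and clock
    grid_n: int = 201
    domain_len: float = 1.0
    h: float = 0.005
    dt: float = 0.002
    n_steps: int = 35000
    tau_hours: float = 16.0
    length_scale_cm: float = 1.0  # documentation only; lengths are scaled by L

    # diffusion coefficients
    dn: float = 5e-6
    dm: float = 5e-6
    da: float = 5e-6
    dc_out: float = 5e-4
    dc_in: float = 2.5e-4

    # reaction rates (``*_std`` values are rescaled by the local oxygen level)
    rho_std: float = 1e-4
    eta: float = 50.0
    kappa_std: float = 1.0
    sigma: float = 0.0
    omega_std: float = 0.6
    phi: float = 0.05
    beta_std: float = 0.025
    psi: float = 0.01

    # oxygen thresholds
    c_hypoxia: float = 0.4
    c_death: float = 0.1

    # vasculature
    p: float = 1.0
    p_c: float = 0.0
    vessel_update_hours: float = 2.0
    vessel_mode: str = "resample"

    # discrete cells
    n_init_cells: int = 81
    age_max_hours: float = 16.0
    mitosis_mode: str = "random_direction"
    hypoxic_arrest: bool = True
    adhesion_enabled: bool = False
    quiescent_uptake_factor: float = 1.0

    seed: int = 0

    # bookkeeping strides (hours); None -> snapshot schedule default
    record_stride_hours: float = 20.0
    snapshot_hours: tuple = (320.0, 480.0, 640.0, 800.0, 960.0, 1120.0)

    def __post_init__(self):
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        g = self.grid_n
        if g < 3:
            raise ConfigError("grid_n: must be >= 3")
        expected_h = self.domain_len / (g - 1)
        if abs(self.h - expected_h) > 1e-12 * max(1.0, expected_h):
            raise ConfigError(
                f"h: inconsistent with lattice, expected domain_len/(grid_n-1)"
                f" = {expected_h!r}, got {self.h!r}"
            )
        for name in (
            "dt", "n_steps", "tau_hours", "dn", "dm", "da", "dc_out", "dc_in",
            "rho_std", "eta", "kappa_std", "sigma", "omega_std", "phi",
            "beta_std", "psi", "p", "vessel_update_hours", "age_max_hours",
            "quiescent_uptake_factor", "record_stride_hours",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if self.dt <= 0:
            raise ConfigError("dt: must be > 0")
        if not (0.0 <= self.c_death < self.c_hypoxia <= 1.0):
            raise ConfigError(
                f"c_death/c_hypoxia: need 0 <= c_death < c_hypoxia <= 1, got "
                f"{self.c_death!r}, {self.c_hypoxia!r}"
            )
        if not (0.0 <= self.p_c <= 1.0):
            raise ConfigError(f"p_c: must be a probability in [0, 1], got {self.p_c!r}")
        if self.vessel_mode not in _VESSEL_MODES:
            raise ConfigError(
                f"vessel_mode: must be one of {_VESSEL_MODES}, got {self.vessel_mode!r}"
            )
        if self.mitosis_mode not in _MITOSIS_MODES:
            raise ConfigError(
                f"mitosis_mode: must be one of {_MITOSIS_MODES}, "
                f"got {self.mitosis_mode!r}"
            )
        if self.n_init_cells < 1:
            raise ConfigError("n_init_cells: must be >= 1")
        cfl = self.cfl_number()
        if cfl > CFL_LIMIT:
            raise ConfigError(
                f"dt: explicit diffusion step unstable, max(D)*dt/h^2 = "
                f"{cfl:.4g} > {CFL_LIMIT}"
            )

    def cfl_number(self) -> float:
        """max(D) * dt / h^2 for the fastest-diffusing field."""
        return max(self.dc_out, self.dc_in, self.dn, self.dm, self.da) * self.dt / self.h**2

    # -- derived quantities ---------------------------------------------

    @property
    def hours_per_step(self) -> float:
        return self.dt * self.tau_hours

    @property
    def total_hours(self) -> float:
        return self.n_steps * self.hours_per_step

    @property
    def center(self) -> tuple:
        """Lattice coordinates of the domain center (row, col)."""
        c = (self.grid_n - 1) / 2.0
        return (c, c)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["snapshot_hours"] = list(self.snapshot_hours)
        return d

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def default_config(**overrides) -> SimulationConfig:
    """The baseline parameter set (keyword overrides re-validated)."""
    return SimulationConfig(**overrides)


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path) -> SimulationConfig:
    """Load a flat key/value (YAML) config document.

    Unknown keys are rejected (a typo must not silently fall back to a
    default); missing keys take their defaults; invariants are enforced.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path}: expected a flat key/value mapping")
    unknown = sorted(set(data) - _FIELD_NAMES)
    if unknown:
        raise ConfigError(f"config file {path}: unknown keys {unknown}")
    if "snapshot_hours" in data:
        data["snapshot_hours"] = tuple(float(x) for x in data["snapshot_hours"])
    return SimulationConfig(**data)


def save_config(config: SimulationConfig, path) -> None:
    """Write a config as a flat YAML document (round-trips via load_config)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: SimulationConfig) -> str:
    """Short stable digest of the full parameter set (provenance tag)."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
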