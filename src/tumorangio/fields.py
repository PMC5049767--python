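"""Explicit forward-Euler updates for the four continuum fields.

The scaled reaction–diffusion system on the unit square is

    df/dt = -eta * m * f                                  (ECM degradation)
    dm/dt = dm * lap(m) + kappa(c) * n - sigma * m        (MDE)
    dc/dt = dc(x) * lap(c) - omega(c) * n - phi * c       (oxygen)
    da/dt = da * lap(a) + beta(c) * n - psi * a           (TAF)

where ``n`` is the discrete live-cell occupancy (0/1 per site), ``lap`` is
the 5-point Laplacian with no-flux (reflecting) boundaries, and the
haptotaxis/uptake/production coefficients rho, omega, kappa scale linearly
with the local oxygen level as ``(3 c + 0.7) * std``.  TAF production is
gated: live cells secrete only when their oxygen is at or below the hypoxia
threshold (0.4 by default, boundary inclusive).

Oxygen diffuses at ``dc_in`` inside the current tumor radius and ``dc_out``
outside; vessel points are Dirichlet sources that pin c to 1 after every
update.  All updates read only previous-step values, so within one time step
the four field updates commute.
"""

from __future__ import annotations

import numpy as np

from .state import FieldState, OccupancyMasks, VesselSet
from .config import SimulationConfig

__all__ = [
    "InstabilityError",
    "laplacian_noflux",
    "beta_of_c",
    "oxygen_scaled",
    "step_ecm",
    "step_mde",
    "step_oxygen",
    "step_taf",
    "step_fields",
]

#: Negative excursions larger than this are treated as numerical instability
#: rather than silently floored.
_FLOOR_TOL = 1e-12


class InstabilityError(RuntimeError):
    """A field update produced values inconsistent with a stable explicit step."""


def laplacian_noflux(field: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with zero-normal-derivative (reflected) boundaries.

    Ghost values equal the edge values, so the discrete operator conserves
    the field sum exactly (no flux leaves the domain).
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    if not np.all(np.isfinite(field)):
        raise InstabilityError("non-finite input to laplacian")
    p = np.pad(field, 1, mode="edge")
    return (
        p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * field
    ) / (h * h)


def beta_of_c(c_value, beta_std: float, c_hypoxia: float):
    """Oxygen-gated TAF production rate: beta_std where c <= c_hypoxia, else 0.

    The boundary is inclusive: a cell sitting exactly at the threshold is
    hypoxic and secretes.  Accepts scalars or arrays.
    """
    return np.where(np.asarray(c_value) <= c_hypoxia, beta_std, 0.0)


def oxygen_scaled(c_value, std_value):
    """Linear oxygen scaling (3c + 0.7) * std applied to rho, omega and kappa.

    No clamping: the law is linear and unbounded above.
    """
    return (3.0 * np.asarray(c_value) + 0.7) * std_value


def step_ecm(f: np.ndarray, m: np.ndarray, eta: float, dt: float) -> np.ndarray:
    """One Euler step of pure ECM degradation, floored at zero.

    A value driven below ``-1e-12`` indicates dt is too large for the local
    eta*m and raises rather than being masked by the floor.
    """
    fn = f * (1.0 - eta * m * dt)
    if fn.min() < -_FLOOR_TOL:
        raise InstabilityError(
            f"ECM step produced {fn.min():.3g} < -{_FLOOR_TOL:g}; "
            "dt too large for local eta*m"
        )
    return np.maximum(fn, 0.0)


def step_mde(m: np.ndarray, masks: OccupancyMasks, c: np.ndarray,
             config: SimulationConfig) -> np.ndarray:
    """One Euler step of the MDE field (diffusion + live-cell production - decay)."""
    kappa = oxygen_scaled(c, config.kappa_std)
    mn = m + config.dt * (
        config.dm * laplacian_noflux(m, config.h)
        + kappa * masks.live_mask
        - config.sigma * m
    )
    if not np.all(np.isfinite(mn)):
        raise InstabilityError("non-finite MDE field")
    return np.maximum(mn, 0.0)


def step_oxygen(c: np.ndarray, masks: OccupancyMasks, vessels: VesselSet,
                config: SimulationConfig) -> np.ndarray:
    """One Euler step of the oxygen field.

    Diffusivity is ``dc_in`` on the tumor interior and ``dc_out`` elsewhere.
    Uptake is 1 per proliferative site and ``quiescent_uptake_factor`` per
    quiescent site (dead and empty sites consume nothing), scaled by the
    oxygen law.  After the update every vessel site is pinned to c = 1
    (Dirichlet source) and the field is clipped at zero.
    """
    dc = np.where(masks.tumor_interior_mask, config.dc_in, config.dc_out)
    uptake_occ = (
        masks.proliferative_mask
        + config.quiescent_uptake_factor * masks.quiescent_mask
    )
    cn = c + config.dt * (
        dc * laplacian_noflux(c, config.h)
        - oxygen_scaled(c, config.omega_std) * uptake_occ
        - config.phi * c
    )
    if not np.all(np.isfinite(cn)):
        raise InstabilityError("non-finite oxygen field")
    cn = np.maximum(cn, 0.0)
    cn[vessels.mask] = 1.0
    return cn


def step_taf(a: np.ndarray, masks: OccupancyMasks, c: np.ndarray,
             config: SimulationConfig) -> np.ndarray:
    """One Euler step of the TAF field with oxygen-gated production."""
    beta = beta_of_c(c, config.beta_std, config.c_hypoxia)
    an = a + config.dt * (
        config.da * laplacian_noflux(a, config.h)
        + beta * masks.live_mask
        - config.psi * a
    )
    if not np.all(np.isfinite(an)):
        raise InstabilityError("non-finite TAF field")
    return np.maximum(an, 0.0)


def step_fields(fields: FieldState, masks: OccupancyMasks, vessels: VesselSet,
                config: SimulationConfig) -> FieldState:
    """Advance all four fields one step, reading only previous-step values."""
    f, m, c, a = fields.f, fields.m, fields.c, fields.a
    return FieldState(
        f=step_ecm(f, m, config.eta, config.dt),
        m=step_mde(m, masks, c, config),
        c=step_oxygen(c, masks, vessels, config),
        a=step_taf(a, masks, c, config),
    )
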