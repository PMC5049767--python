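# Model and methods

`tumorangio` simulates the coupled growth of a solid tumor and its
capillary supply on a two-dimensional lattice. It is a hybrid model: the
tumor microenvironment is continuum (reaction–diffusion fields), the tumor
cells are discrete agents, and the vasculature is a stochastic point
process driven by one of the fields.

## Continuum fields

Four non-dimensional fields live on an `N x N` lattice over the unit
square (default `N = 201`, spacing `h = 0.005`), advanced by explicit
forward Euler with time step `dt = 0.002`:

    df/dt = -eta * m * f                               ECM degradation
    dm/dt = dm ∇²m + kappa(c) * n - sigma * m          matrix-degrading enzyme
    dc/dt = dc(x) ∇²c - omega(c) * n - phi * c         oxygen
    da/dt = da ∇²a + beta(c) * n - psi * a             tumor angiogenic factor

`n` is the discrete live-cell occupancy (0/1 per site; dead cells are
inert). The Laplacian is the 5-point stencil with reflected (no-flux)
ghost values, so each diffusion operator conserves its field's sum
exactly. Time and space are scaled by one cell cycle `tau = 16 h` and a
domain size `L = 1 cm`; one run of 35,000 steps covers 1120 h.

Oxygen dependence enters three coefficients linearly,
`rho, omega, kappa = (3c + 0.7) * std`, unclamped (the law is linear in
the regime the simulation visits). TAF production is gated:
`beta(c) = beta_std` for `c <= c_hypoxia` (threshold inclusive, default
0.4) and 0 otherwise. Oxygen diffuses at `dc_in = 2.5e-4` inside the
current tumor radius and `dc_out = 5e-4` outside, and is pinned to 1 at
every vessel site after each update (Dirichlet sources). The explicit
scheme is comfortably stable: `max(D) dt/h² = 0.04` against a 0.25 bound,
checked at configuration time.

Default rates: `dn = dm = da = 5e-6`, `rho_std = 1e-4`, `eta = 50`,
`kappa_std = 1`, `sigma = 0`, `omega_std = 0.6`, `phi = 0.05`,
`beta_std = 0.025`, `psi = 0.01`.

## Discrete cells

Each lattice site holds at most one cell. A cell is `proliferative`,
`quiescent` or `dead`; per step, in a freshly randomised cell order:

* `c < 0.1` kills (irreversible; the corpse keeps occupying its site);
* a live cell with no empty von-Neumann neighbor is quiescent; quiescence
  is re-evaluated every step, so cells reactivate when space frees;
* proliferative cells move and divide; quiescent and dead cells are inert.

Ages advance by `dt * tau = 0.032 h` per step; initial ages are
Uniform(0, 16) h. A proliferative cell whose age reaches 16 h attempts one
division: the division axis is drawn uniformly among the four von-Neumann
directions, and the attempt fails — consuming the cycle — when the target
site is occupied or off-grid. This graded contact inhibition (a cell with
one free neighbor succeeds in a quarter of its cycles) is what keeps rim
expansion in the sub-site-per-cycle regime of a compact tumor; the
alternative `any_empty` placement (daughter always placed when any
neighbor is free) is kept as a config option and roughly quadruples
late-time cell counts.

**Oxygen checkpoint (`hypoxic_arrest`, default on).** Completing mitosis
additionally requires `c > c_hypoxia`; under hypoxia the division aborts
and the cycle restarts. This is the model's representation of
hypoxia-induced cell-cycle arrest, and it supplies the avascular growth
limit: the background oxygen decays as `exp(-phi t)` and crosses 0.4 at
t ≈ 18.3 time units (≈ 290 h), so without angiogenesis the whole tumor
stops cycling in that window, while cells near vessel points keep
dividing. Without this gate the model has no mechanism by which vascular
supply limits growth, and cell counts overshoot by several fold.

Movement follows the discretised cell-density equation: with
`k = dt/h²` and central (boundary-clamped) differences of the ECM,

    p_right = k [dn + (rho/4)(f_E - f_W)],   p_left = k [dn - ...], etc.

negative coefficients are clamped and the five outcomes renormalised.
Haptotaxis therefore biases motion up the ECM gradient; moves into
occupied or off-grid sites are cancelled. An optional adhesion rule
(`adhesion_enabled`, off by default) additionally rejects moves that
would leave the cell without a live neighbor.

The cell phase is executed by a numba kernel over flat arrays; a
per-cell pure-Python reference implementation of the identical rules is
kept in `tumorangio.cells` and the test suite verifies the two produce
bit-identical trajectories. All randomness is drawn from one
`numpy.random.Generator` in a fixed documented order (ECM, ages; then per
step: permutation, mitosis uniforms, movement uniforms; vessel lattice on
refresh steps), so a (config, seed) pair reproduces a run bit-for-bit.

## Vasculature

Vessels are lattice points (capillary cross-sections), not tracked
sprouts. Every 2 simulated hours the vessel set is resampled: each site
independently receives a point with probability

    P_b = p_c                  if r/r0 <= 0.5
        = min(1, p * a)        otherwise,

with `p = 1`, `p_c = 0` by default. `r0` is the tumor radius — the 95th
percentile of live-cell distances from the all-cell centroid, floored at
one lattice spacing — recomputed at each refresh, along with the
interior-diffusivity mask. With `p_c = 0` the inner half-radius is
vessel-free by construction at every refresh, which produces the necrotic
core. Full resampling (capillaries as transient structures) is the
default; an `accumulate` mode that only adds points is available for
comparison. The 2 h interval is 62.5 steps, so refreshes alternate
between 62 and 63 steps on a fixed 2-hour schedule grid.

Because TAF is secreted only by hypoxic live cells and decays away from
the tumor, vessel probability is effectively confined to a perivascular
annulus around the hypoxic mass; no explicit spatial restriction is
imposed.

## Emergent structure

A default run passes through an avascular phase (cluster growth while
ambient oxygen lasts), hypoxia and TAF secretion (~100–300 h), vessel
formation outside the half-radius, and sustained vascular growth. At
1120 h the tumor shows the canonical three concentric zones — necrotic
core (dead-dominated, vessel-free), quiescent middle, proliferative rim —
with the radial vessel density rising from exactly zero at `r/r0 = 0.5`
to a peak of ~13% of annulus sites and falling off at the tumor edge.
With ~4 replicate seeds, surviving cells at 1120 h are ~4500 ± 220,
quiescent ~3950 ± 210, capillary points ~340 ± 9 (numbers as computed by
`scripts/acceptance.py`; see the README for how to regenerate them).

Two readouts sit outside the reference regime and are reported as such by
the acceptance tests: the proliferative count (this model's compact rim
leaves fewer cells with free space than the reference's ~25% of live
cells) and the dead count (with the published uptake law
`-omega(c) * n`, which does not vanish as `c -> 0`, oxygen penetrates
only ~3 sites past the vessel-free boundary, giving a necrotic radius of
~0.4 r0 instead of ~0.32 r0). Both trace to discrete-cell rules the
source literature specifies only by reference; the surrounding totals,
profiles and all sensitivity directions are reproduced.

## Sensitivity behaviour

* `p_c = 0.1` (vessels admitted into the core): dead count collapses to
  ~0, the survival gain is almost entirely quiescent (the rescued centre
  has no space), proliferative count changes little, vessel count roughly
  doubles.
* `p = 2`: vessel count rises proportionally more (+~90%) than live cells
  (+~60%) — the rim oxygen supply is near saturation at `p = 1`.
* `p = 0, p_c = 0`: no oxygen source exists at all, so the live count
  stops rising and the population eventually dies out; the comparison
  demonstrates the angiogenesis rescue (the default run is still growing
  at 1120 h and ends far higher).

## Numerical and degenerate-input choices

* Fields are floored at 0; an ECM update that would go below `-1e-12`
  raises an instability error instead of being masked.
* `n_init_cells` must be a perfect square; the initial cluster is a
  centered k x k block (81 cells -> 9x9 around site (100, 100)).
* A single-cell tumor has `r0 = h` (floor); the radial profile rejects
  `r0 = 0`.
* The time-series stride (20 h) and snapshot epochs (320…1120 h) are
  configurable bookkeeping only.
* Problem sizes in the test suite: unit tests run on 5–51 site lattices;
  the end-to-end tests and the acceptance script run the full 201x201,
  35,000-step protocol (about a minute per run compiled).

## What the generator does and does not emulate

All inputs are generated internally: the i.i.d. Uniform(0,1) ECM field,
the 81-cell cluster with Uniform(0,16) h ages, and the stochastic vessel
draws. The model does not represent endothelial-cell migration, vessel
connectivity or blood flow (vessel points are independent Bernoulli draws
each refresh), convective transport, cell mutation, or mechanical
pushing; passing tests therefore say nothing about those processes. Cell
state is the only phenotype; there is no subcellular cycle model beyond
the age clock and the oxygen checkpoint.
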