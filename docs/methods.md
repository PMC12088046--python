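# Methods

## Physical model

`rotaseed` models a rigid spherical cell (or microcarrier bead) suspended in
a cylindrical lumen whose fluid rotates as a solid body with the wall,
v_θ = rω. The assumption is justified by the rotational Reynolds number of
the seeding condition, Re = ρ_f(ωR)(2R)/μ ≈ 0.016 at 24 rev/h in a 0.04 cm
lumen: secondary flows are absent and the fluid velocity field is taken as
unaffected by the cell.

Forces on the particle:

- **Stokes drag** −6πμa(v − v_fluid) on the slip velocity relative to the
  local solid-body fluid velocity. Valid at particle Reynolds numbers ≪ 1,
  which holds for both the 7.5 µm cell (slip ~10⁻³ cm/s) and the 330 µm
  bead (slip ~10 cm/s, Re_p ~0.7 — marginal but standard for this kind of
  trajectory analysis).
- **Buoyancy-corrected gravity** (m − mₚ)g ŷ with m = ρ_f Vₚ the
  displaced-fluid mass; for a cell denser than medium this is a net
  downward force ΔρVₚg.
- **Pressure-gradient + virtual-mass forces** of the rotating fluid,
  −m(Cᵥ+1)rω² r̂, pointing toward the axis. The virtual-mass coefficient
  Cᵥ = 0.5 (sphere) also augments the inertia: M = mₚ + Cᵥm.

In polar coordinates (x = r cosθ, y = r sinθ, gravity along −y,
counter-clockwise rotation):

    M(dv_r/dt − r θ̇²) = −m(Cᵥ+1) r ω² + (m−mₚ) g sinθ − 6πμa v_r
    M(r θ̈ + 2 v_r θ̇)  =  (m−mₚ) g cosθ − 6πμa r (θ̇ − ω)

Both equations are derived from the force inventory above by resolving
Newton's second law into radial and transverse components; the derivation
is validated by reproducing the known wall-contact patterns at 15, 20, 24
and 30 rev/h (see below). In Cartesian coordinates the same system is
*linear* in (x, y, vx, vy) and regular at the axis, so the integrator works
in Cartesian state and converts to polar for reporting; the polar form of
`equations_of_motion` regularizes the 1/r in the transverse equation below
r = 10⁻⁶ cm so direct evaluation at the axis never divides by zero.

## Numerical integration

The system is stiff: the momentum relaxation time τ = M/(6πμa) is ~2×10⁻⁵ s
for the cell against a ~150 s rotation period (ratio ~10⁷). The default
solver is LSODA (adaptive, switches to BDF in the stiff regime) with
rtol = 10⁻⁸ and atol = 10⁻¹⁴; at these tolerances the spurious numerical
drift of a closed cell orbit is below 10⁻⁸ cm per revolution, two orders
under the 10⁻⁶ cm closed-orbit criterion. Wall contact is a terminal
`solve_ivp` event on r − r_contact with positive crossing direction; the
event state is appended to the sampled path so trajectories end exactly on
the wall. Output is sampled at 400 points per revolution (configurable).

Defaults, with rationale:

- **Contact criterion**: centre reaches the lumen radius R (r ≥ R). The
  alternative, surface touch at r ≥ R − a, is configurable; for the 7.5 µm
  cell in the 0.04 cm lumen the two differ by under 2 % in radius and do
  not change any of the 15/20/24/30 rev/h patterns.
- **Initial motion**: co-rotating with the fluid (v_r = 0, θ̇ = ω). The
  velocity transient decays within τ ≪ 1 ms, so the choice is immaterial
  beyond the first millisecond; an at-rest start is available.
- **Time horizon**: 3 revolutions. Cell-scale orbits are closed after the
  first revolution (drift < 10⁻⁶ cm/rev), so a trajectory that misses the
  wall in 3 revolutions misses it forever. For ω = 0 (overdamped settling)
  the horizon is the lumen-crossing settling time instead.
- **Start angle 90°** is the top of the lumen, directly above the axis —
  under the overdamped geometry this is the reading consistent with the
  contact patterns across speeds.
- Everything is deterministic; grid ensembles (e.g. for deposition-angle
  histograms) use fixed grids.

## Overdamped closed form (oracle)

With inertia dropped, the particle velocity is fluid velocity plus Stokes
settling velocity w = 2Δρga²/(9μ). In complex position z = x + iy this is
ż = iω(z − w/ω): a circle about the fixed point c = w/ω traversed at ω, so
the maximum axis distance is |c| + |z₀ − c| and wall contact and its time
follow from circle geometry in closed form. `overdamped_orbit` refuses to
run unless τ < 10⁻³ × the rotation period (regime guard). For the cell
presets, full-ODE and closed-form paths agree within ~10⁻⁶ of the lumen
radius — the primary verification of the integrator, asserted at 1 % of R
in the tests.

The test suite adds a second, fully independent oracle valid in *every*
inertia regime: the exact solution of the linear Cartesian system by
eigendecomposition (M z̈ + Dż + (m(1+Cᵥ)ω² − iDω)z = i(m−mₚ)g). The
microcarrier benchmark is checked against it to 10⁻⁴ cm on a 5 cm vessel.

## Microcarrier benchmark and its revolution budget

The model-validation case — a 330 µm bead, ρₚ = 1.3 g/cm³, μ = 0.01
g/(cm·s), 35 rev/min, 5 cm vessel, start at r = 0.5 cm above the axis — is
inertial (τ ≈ 0.04 s, ωτ ≈ 0.16). Its slow eigenvalue has a positive real
part: the orbit is an outward exponential spiral growing ≈16 % per
revolution. Starting 0.5 cm above the axis puts the bead on an orbit of
radius ≈2.0 cm about the offset centre (1.91, −0.25) cm, so the maximum
excursion reaches the 5 cm wall at t ≈ 5.93 s ≈ 3.46 revolutions: with
these parameters the bead completes exactly 3 full revolutions before
contact. The orbit-averaged radius strictly increases over every completed
revolution (2.667 → 2.960 → 3.322 cm), and reversing the density difference
(a bead lighter than the fluid) reverses the drift to inward — the two
qualitative signatures the benchmark is meant to show. A longer outward
spiral would require a smaller density difference, a slower vessel, or a
start closer to the offset centre; the benchmark parameters are kept as
printed.

## Adhesion force balance

For a cell already attached at the wall, the rotational drag is evaluated
as Stokes drag at the wall speed, F = 6πμa(Rω), and the gravity load as
F = mₚg·cos(θ/2) with θ measured from the lumen top (maximal at θ = 0,
zero at θ = π). The gravity load deliberately uses the full cell mass, not
the buoyancy-corrected mass: it is the conventional worst-case load on the
adhesion. The two detachment thresholds (1.57×10⁻¹¹ N for 0.01 Pa,
1.57×10⁻¹⁰ N for 0.1 Pa) are literature constants stored as named values —
the cell-geometry model behind them is not re-derived here. Forces are
computed in dynes and reported in newtons (1 dyn = 10⁻⁵ N). No bond-level
kinetics are modelled; safety is a scalar comparison.

The angle θ in this force balance is the lumen-surface position angle of
an adherent cell and is defined independently of the trajectory module's
polar angle; the two conventions are not interconverted.

## Perfusion schedules

Wall shear stress uses the steady Poiseuille form τ = 4μQ/(πR³), the
standard result for laminar flow in a cylindrical conduit, converted to Pa.
With nominal medium viscosity 0.0085 g/(cm·s) and R = 0.04 cm, 0.5 mL/min
gives τ ≈ 0.14 Pa; the experimentally quoted pairing of 0.5 mL/min with
0.4 Pa therefore implies a different effective viscosity (≈0.024 g/(cm·s),
e.g. a supplemented medium) or radius. The module exposes both parameters
and honours the nominal pairing as a preset without asserting its physics.

Ramp schedules interpolate stress linearly between start and target by
default (geometric available); the first step is exactly the start stress,
the last exactly the target, and each step carries the flow rate from the
exact inverse of the shear formula. A rapid-start schedule is a single step
at the target. The percent-circumferential-coverage statistic,
100·Σ(covered arc lengths)/perimeter, tolerates a 0.5 % tracing overshoot
(clipped to 100 %) and rejects anything larger as inconsistent data.

## Problem sizes

The shipped analyses are small by construction: contact maps are
4 speeds × 4 radii (16 trajectories of ≤3 revolutions each), the speed
sweep is 21 speeds × 4 radii, and each trajectory integrates in tens of
milliseconds; the full test suite and the results script each run in
seconds.

## What the tests do and do not show

The simulator is verified against closed forms, scaling laws, and two
independent analytic oracles, and reproduces the known contact patterns of
the seeding study. It does not model particle–particle interactions, wall
lubrication corrections, post-contact rolling or adhesion kinetics, axial
(3-D) motion, or non-Newtonian media — so passing tests establish the
fidelity of the idealized single-particle physics, not outcomes of real
seeding runs, which also depend on cell concentration, adhesion biology,
and hardware tolerances.
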