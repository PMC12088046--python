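"""Trajectory of a dense sphere in a solid-body-rotating fluid, with wall contact.

The cell is treated as a rigid sphere in Stokes flow inside a lumen whose
fluid co-rotates with the wall (v_θ = rω).  Newton's second law with the
effective (virtual-mass-augmented) inertia M = mₚ + Cᵥm gives, in polar
coordinates with gravity along −y and counter-clockwise rotation:

    radial:      M(dv_r/dt − r θ̇²) = −m(Cᵥ+1) r ω²  + (m−mₚ) g sinθ − 6πμa v_r
    transverse:  M(r θ̈ + 2 v_r θ̇) =  (m−mₚ) g cosθ − 6πμa r (θ̇ − ω)

where m = ρ_f Vₚ is the displaced-fluid mass.  The −m(Cᵥ+1)rω² term bundles
the fluid pressure-gradient force with the fluid-acceleration part of the
virtual-mass force; the drag is Stokes drag on the slip velocity relative to
the rotating fluid; gravity is buoyancy-corrected ((m−mₚ) = −ΔρVₚ).

The same force inventory in Cartesian coordinates is a *linear* ODE and is
regular at r = 0, so the numerical integrator works in Cartesian state
(x, y, vx, vy) and converts back to polar for reporting.  Wall contact is
located by terminal event detection on |x| crossing the contact radius.

For the cell-scale parameters the momentum relaxation time M/(6πμa) is
~2e-5 s against a ~150 s rotation period, so inertia is negligible and the
trajectory collapses to a closed-form circle: the particle rides the fluid
rotation while settling at the Stokes velocity w, which is a circular orbit
about a centre displaced w/ω horizontally from the rotation axis.
:func:`overdamped_orbit` implements this closed form and serves as an
independent oracle for the full integration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .physics import RotationScenario, settling_velocity

__all__ = [
    "ContactCriterion",
    "InitialMotion",
    "SolverMode",
    "SimConfig",
    "TrajectoryState",
    "TrajectoryResult",
    "IntegrationError",
    "RegimeError",
    "equations_of_motion",
    "simulate_trajectory",
    "overdamped_orbit",
    "microcarrier_scenario",
    "replicate_microcarrier_case",
]

# below this radius the polar transverse equation is regularized (see
# equations_of_motion); the Cartesian integrator itself has no singularity
_R_POLAR_EPS = 1.0e-6


class ContactCriterion(enum.Enum):
    """When a trajectory counts as having reached the wall."""

    #: particle centre reaches the lumen radius R (dashed-wall-line convention)
    CENTER_REACHES_WALL = "center_reaches_R"
    #: particle surface touches the wall: centre reaches R − a
    SURFACE_TOUCHES_WALL = "surface_touch_R_minus_a"


class InitialMotion(enum.Enum):
    """Initial particle velocity convention.

    The velocity transient decays within the ~2e-5 s relaxation time, far
    below anything resolvable at seeding time scales, so co-rotating with
    the fluid is the default.
    """

    CO_ROTATING = "co_rotating"
    AT_REST = "at_rest"


class SolverMode(enum.Enum):
    FULL_ODE = "full_ode"
    OVERDAMPED = "overdamped"


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last valid state reached."""

    def __init__(self, message: str, last_state: Optional["TrajectoryState"] = None):
        super().__init__(message)
        self.last_state = last_state


class RegimeError(ValueError):
    """The overdamped closed form was requested outside its validity regime."""


@dataclass(frozen=True)
class TrajectoryState:
    """Instantaneous particle state in polar coordinates.

    ``r`` cm, ``theta`` rad (x = r cosθ, y = r sinθ, gravity along −y),
    ``v_r`` cm/s, ``theta_dot`` rad/s.
    """

    r: float
    theta: float
    v_r: float = 0.0
    theta_dot: float = 0.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"r must be >= 0, got {self.r}")
        for name in ("r", "theta", "v_r", "theta_dot"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class SimConfig:
    """Integration and contact-detection settings.

    max_revolutions:
        Time horizon in rotation periods (2π/ω each).
    rel_tolerance / abs_tolerance:
        Solver tolerances.  The full system is stiff (relaxation time
        ~1e-5 s against ~1e2 s periods); LSODA switches to BDF
        automatically and the defaults resolve per-revolution orbit drift
        well below 1e-6 cm for the cell-scale presets.
    samples_per_revolution:
        Output sampling density.
    """

    max_revolutions: int = 3
    rel_tolerance: float = 1.0e-8
    abs_tolerance: float = 1.0e-14
    contact_criterion: ContactCriterion = ContactCriterion.CENTER_REACHES_WALL
    initial_motion: InitialMotion = InitialMotion.CO_ROTATING
    solver_mode: SolverMode = SolverMode.FULL_ODE
    samples_per_revolution: int = 400

    def __post_init__(self) -> None:
        if self.max_revolutions < 1:
            raise ValueError("max_revolutions must be >= 1")
        if self.rel_tolerance <= 0 or self.abs_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.samples_per_revolution < 2:
            raise ValueError("samples_per_revolution must be >= 2")


def contact_radius(scenario: RotationScenario, criterion: ContactCriterion) -> float:
    """Radial coordinate at which the active contact criterion fires."""
    R = scenario.vessel.lumen_radius_R
    if criterion is ContactCriterion.SURFACE_TOUCHES_WALL:
        return R - scenario.particle.radius_a
    return R


@dataclass
class TrajectoryResult:
    """Time-sampled path with the wall-contact outcome.

    ``theta_rad`` is the unwrapped (continuous) polar angle; the contact
    angle is reported wrapped to [0, 2π).  ``revolution_mean_radii_cm``
    holds the mean axis distance over each *completed* rotation period,
    and ``orbit_drift_per_revolution_cm`` the mean change between
    consecutive periods (NaN when fewer than two were completed) — the
    diagnostic for closed orbits (cells) vs outward spirals (large beads).
    """

    time_s: np.ndarray
    r_cm: np.ndarray
    theta_rad: np.ndarray
    v_r_cm_s: np.ndarray
    theta_dot_rad_s: np.ndarray
    contacted_wall: bool
    contact_time_s: Optional[float]
    contact_angle_rad: Optional[float]
    scenario: RotationScenario
    config: SimConfig

    @property
    def x_cm(self) -> np.ndarray:
        return self.r_cm * np.cos(self.theta_rad)

    @property
    def y_cm(self) -> np.ndarray:
        return self.r_cm * np.sin(self.theta_rad)

    @property
    def n_revolutions_completed(self) -> int:
        omega = self.scenario.omega
        if omega <= 0:
            return 0
        return int(self.time_s[-1] / (2.0 * math.pi / omega))

    @property
    def revolution_mean_radii_cm(self) -> np.ndarray:
        omega = self.scenario.omega
        if omega <= 0:
            return np.array([])
        T = 2.0 * math.pi / omega
        means = []
        for k in range(self.n_revolutions_completed):
            mask = (self.time_s >= k * T) & (self.time_s < (k + 1) * T)
            if mask.sum() >= 2:
                means.append(float(self.r_cm[mask].mean()))
        return np.asarray(means)

    @property
    def orbit_drift_per_revolution_cm(self) -> float:
        means = self.revolution_mean_radii_cm
        if means.size < 2:
            return math.nan
        return float(np.diff(means).mean())

    def final_state(self) -> TrajectoryState:
        return TrajectoryState(
            r=float(self.r_cm[-1]),
            theta=float(self.theta_rad[-1] % (2.0 * math.pi)),
            v_r=float(self.v_r_cm_s[-1]),
            theta_dot=float(self.theta_dot_rad_s[-1]),
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "r_cm": self.r_cm,
                "theta_rad": self.theta_rad,
                "x_cm": self.x_cm,
                "y_cm": self.y_cm,
                "v_r_cm_s": self.v_r_cm_s,
                "theta_dot_rad_s": self.theta_dot_rad_s,
            }
        )

    def metadata(self) -> dict:
        s = self.scenario
        return {
            "particle": {
                "radius_a_cm": s.particle.radius_a,
                "density_rho_p_g_cm3": s.particle.density_rho_p,
                "virtual_mass_Cv": s.particle.virtual_mass_Cv,
            },
            "fluid": {
                "viscosity_mu_g_cm_s": s.fluid.viscosity_mu,
                "density_rho_f_g_cm3": s.fluid.density_rho_f,
            },
            "vessel": {
                "lumen_radius_R_cm": s.vessel.lumen_radius_R,
                "length_L_cm": s.vessel.length_L,
            },
            "omega_rad_s": s.omega,
            "gravity_g_cm_s2": s.gravity_g,
            "config": {
                "max_revolutions": self.config.max_revolutions,
                "rel_tolerance": self.config.rel_tolerance,
                "abs_tolerance": self.config.abs_tolerance,
                "contact_criterion": self.config.contact_criterion.value,
                "initial_motion": self.config.initial_motion.value,
                "solver_mode": self.config.solver_mode.value,
            },
            "contacted_wall": self.contacted_wall,
            "contact_time_s": self.contact_time_s,
            "contact_angle_rad": self.contact_angle_rad,
            "orbit_drift_per_revolution_cm": self.orbit_drift_per_revolution_cm,
        }


def _cartesian_acceleration(
    x: float, y: float, vx: float, vy: float, scenario: RotationScenario
) -> tuple[float, float]:
    """Acceleration of the particle from the full force inventory, Cartesian."""
    m = scenario.displaced_mass
    mp = scenario.particle.mass_mp
    M = scenario.effective_mass
    Cv = scenario.particle.virtual_mass_Cv
    drag = scenario.stokes_drag_coefficient
    om = scenario.omega
    g = scenario.gravity_g
    # solid-body fluid velocity (counter-clockwise): u = ω ẑ × x
    ufx = -om * y
    ufy = om * x
    ax = (-m * (Cv + 1.0) * om**2 * x - drag * (vx - ufx)) / M
    ay = (-m * (Cv + 1.0) * om**2 * y + (m - mp) * g - drag * (vy - ufy)) / M
    return ax, ay


def equations_of_motion(
    state: TrajectoryState, scenario: RotationScenario
) -> tuple[float, float, float, float]:
    """Time derivatives (dr/dt, dθ/dt, dv_r/dt, dθ̇/dt) of the polar state.

    Implements the radial/transverse equations in the module docstring.
    Near the axis (r < 1e-6 cm) the transverse equation is singular in
    polar form; the radius in its denominator is regularized so the call
    never divides by zero.  The trajectory integrator avoids the issue
    entirely by working in Cartesian coordinates.
    """
    r, th, vr, thd = state.r, state.theta, state.v_r, state.theta_dot
    m = scenario.displaced_mass
    mp = scenario.particle.mass_mp
    M = scenario.effective_mass
    Cv = scenario.particle.virtual_mass_Cv
    drag = scenario.stokes_drag_coefficient
    om = scenario.omega
    g = scenario.gravity_g

    f_r = -m * (Cv + 1.0) * om**2 * r + (m - mp) * g * math.sin(th) - drag * vr
    f_th = (m - mp) * g * math.cos(th) - drag * r * (thd - om)
    dvr_dt = f_r / M + r * thd**2
    r_safe = max(r, _R_POLAR_EPS)
    dthd_dt = (f_th / M - 2.0 * vr * thd) / r_safe
    return (vr, thd, dvr_dt, dthd_dt)


def _initial_cartesian(
    initial: TrajectoryState, scenario: RotationScenario, motion: InitialMotion
) -> np.ndarray:
    x0 = initial.r * math.cos(initial.theta)
    y0 = initial.r * math.sin(initial.theta)
    if motion is InitialMotion.CO_ROTATING:
        om = scenario.omega
        vx0, vy0 = -om * y0, om * x0
    else:
        vx0 = initial.v_r * math.cos(initial.theta) - initial.r * initial.theta_dot * math.sin(initial.theta)
        vy0 = initial.v_r * math.sin(initial.theta) + initial.r * initial.theta_dot * math.cos(initial.theta)
    return np.array([x0, y0, vx0, vy0])


def _time_horizon(scenario: RotationScenario, config: SimConfig, r_contact: float) -> float:
    om = scenario.omega
    if om > 0:
        return config.max_revolutions * 2.0 * math.pi / om
    w = settling_velocity(scenario.particle, scenario.fluid, scenario.gravity_g)
    if w == 0:
        raise ValueError("omega = 0 and neutrally buoyant particle: no motion to simulate")
    # pure settling: time to cross the whole lumen, with margin
    return config.max_revolutions * 2.0 * r_contact / abs(w)


def _result_from_cartesian(
    t: np.ndarray,
    xy: np.ndarray,
    scenario: RotationScenario,
    config: SimConfig,
    contacted: bool,
    contact_time: Optional[float],
) -> TrajectoryResult:
    x, y, vx, vy = xy
    r = np.hypot(x, y)
    theta = np.unwrap(np.arctan2(y, x))
    with np.errstate(invalid="ignore", divide="ignore"):
        v_r = np.where(r > 0, (x * vx + y * vy) / r, np.hypot(vx, vy))
        theta_dot = np.where(r > 0, (x * vy - y * vx) / r**2, 0.0)
    contact_angle = float(theta[-1] % (2.0 * math.pi)) if contacted else None
    return TrajectoryResult(
        time_s=t,
        r_cm=r,
        theta_rad=theta,
        v_r_cm_s=v_r,
        theta_dot_rad_s=theta_dot,
        contacted_wall=contacted,
        contact_time_s=contact_time,
        contact_angle_rad=contact_angle,
        scenario=scenario,
        config=config,
    )


def simulate_trajectory(
    initial: TrajectoryState,
    scenario: RotationScenario,
    config: SimConfig = SimConfig(),
) -> TrajectoryResult:
    """Integrate the equations of motion until wall contact or the time horizon.

    The stiff linear system is integrated with LSODA (adaptive, switches to
    BDF when stiff) on the Cartesian form, with a terminal event on the
    contact radius.  The initial radial position must lie strictly inside
    the contact radius.
    """
    if config.solver_mode is SolverMode.OVERDAMPED:
        return overdamped_orbit(initial, scenario, config)

    r_c = contact_radius(scenario, config.contact_criterion)
    if initial.r >= r_c:
        raise ValueError(f"initial radius {initial.r} must be < contact radius {r_c}")

    y0 = _initial_cartesian(initial, scenario, config.initial_motion)
    t_end = _time_horizon(scenario, config, r_c)

    def rhs(t, y):
        ax, ay = _cartesian_acceleration(y[0], y[1], y[2], y[3], scenario)
        return [y[2], y[3], ax, ay]

    def hit_wall(t, y):
        return math.hypot(y[0], y[1]) - r_c

    hit_wall.terminal = True
    hit_wall.direction = 1

    n_samples = config.max_revolutions * config.samples_per_revolution + 1
    t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        rtol=config.rel_tolerance,
        atol=config.abs_tolerance,
        t_eval=t_eval,
        events=hit_wall,
    )
    if not sol.success:
        last = None
        if sol.y.shape[1] > 0:
            x, y_, vx, vy = sol.y[:, -1]
            r_last = math.hypot(x, y_)
            last = TrajectoryState(
                r=r_last,
                theta=math.atan2(y_, x) % (2.0 * math.pi),
                v_r=(x * vx + y_ * vy) / r_last if r_last > 0 else 0.0,
                theta_dot=(x * vy - y_ * vx) / r_last**2 if r_last > 0 else 0.0,
            )
        raise IntegrationError(f"ODE integration failed: {sol.message}", last_state=last)

    contacted = sol.t_events[0].size > 0
    t = sol.t
    xy = sol.y
    contact_time = None
    if contacted:
        contact_time = float(sol.t_events[0][0])
        # append the exact event state so the path ends on the wall
        if t.size == 0 or t[-1] < contact_time:
            t = np.append(t, contact_time)
            xy = np.column_stack([xy, sol.y_events[0][0]]) if xy.size else sol.y_events[0][0][:, None]
    return _result_from_cartesian(t, xy, scenario, config, contacted, contact_time)


def overdamped_orbit(
    initial: TrajectoryState,
    scenario: RotationScenario,
    config: SimConfig = SimConfig(solver_mode=SolverMode.OVERDAMPED),
) -> TrajectoryResult:
    """Closed-form inertia-free trajectory, the analytic oracle.

    In the overdamped limit the particle velocity is the fluid velocity
    plus the Stokes settling velocity w.  Writing positions as complex
    z = x + iy, ż = iωz − iw, whose solution is a circle about the fixed
    point c = w/ω (offset horizontally from the axis, on the side where
    settling opposes the upward-moving fluid):

        z(t) = c + (z₀ − c)·e^{iωt}

    Maximum axis distance is |c| + |z₀ − c|; wall contact and its timing
    are found exactly from the circle geometry.  For ω = 0 the path is a
    vertical settling line.  Raises :class:`RegimeError` unless the
    relaxation time is below 1e-3 of the rotation period (or of the
    lumen-crossing settling time when ω = 0).
    """
    om = scenario.omega
    w = settling_velocity(scenario.particle, scenario.fluid, scenario.gravity_g)
    r_c = contact_radius(scenario, config.contact_criterion)
    if initial.r >= r_c:
        raise ValueError(f"initial radius {initial.r} must be < contact radius {r_c}")

    tau = scenario.relaxation_time
    if om > 0:
        period = 2.0 * math.pi / om
    else:
        if w == 0:
            raise ValueError("omega = 0 and neutrally buoyant particle: no motion")
        period = 2.0 * r_c / abs(w)
    if tau >= 1.0e-3 * period:
        raise RegimeError(
            f"overdamped form invalid: relaxation time {tau:.3g} s is not "
            f"<= 1e-3 x characteristic time {period:.3g} s"
        )

    z0 = initial.r * complex(math.cos(initial.theta), math.sin(initial.theta))
    t_end = _time_horizon(scenario, config, r_c)
    n_samples = config.max_revolutions * config.samples_per_revolution + 1

    if om == 0:
        # pure settling along -y: contact when the vertical line meets the circle
        x0, y0 = z0.real, z0.imag
        y_hit = -math.sqrt(max(r_c**2 - x0**2, 0.0))
        t_hit = (y0 - y_hit) / w if w > 0 else math.inf
        contacted = math.isfinite(t_hit) and t_hit <= t_end
        t_stop = min(t_hit, t_end) if contacted else t_end
        t = np.linspace(0.0, t_stop, n_samples)
        z = z0 - 1j * w * t
        zdot = np.full_like(z, -1j * w)
        return _overdamped_result(t, z, zdot, scenario, config, contacted,
                                  float(t_hit) if contacted else None)

    c = w / om  # orbit centre offset (cm), on the +x side for CCW rotation
    d = abs(z0 - c)
    max_excursion = abs(c) + d
    contacted = max_excursion >= r_c
    t_hit = None
    if contacted:
        if abs(z0) >= r_c:
            t_hit = 0.0
        elif c == 0 or d == 0:
            contacted = False  # stationary radius, cannot newly reach the wall
        else:
            # |z(t)|² = c² + d² + 2cd·cos(ωt + ψ) with ψ = arg(z₀ − c)
            K = (r_c**2 - c**2 - d**2) / (2.0 * abs(c) * d)
            K = min(max(K, -1.0), 1.0)
            phi = math.acos(K)
            psi = math.atan2((z0 - c).imag, (z0 - c).real)
            if c < 0:
                psi += math.pi  # fold the sign of c into the phase
            cands = []
            for sgn in (+1.0, -1.0):
                base = (sgn * phi - psi) / om
                k0 = math.ceil(-base * om / (2.0 * math.pi))
                cands.append(base + k0 * 2.0 * math.pi / om)
            t_hit = min(cand for cand in cands if cand >= -1e-12)
            t_hit = max(t_hit, 0.0)
            if t_hit > t_end:
                contacted = False
                t_hit = None
    t_stop = t_hit if contacted and t_hit is not None else t_end
    t = np.linspace(0.0, t_stop, n_samples)
    z = c + (z0 - c) * np.exp(1j * om * t)
    zdot = 1j * om * (z - c)
    return _overdamped_result(t, z, zdot, scenario, config, contacted, t_hit)


def _overdamped_result(t, z, zdot, scenario, config, contacted, t_hit):
    x, y = z.real, z.imag
    vx, vy = zdot.real, zdot.imag
    xy = np.vstack([x, y, vx, vy])
    return _result_from_cartesian(t, xy, scenario, config, contacted, t_hit)


def microcarrier_scenario(
    speed_rpm: float = 35.0,
    bead_radius_cm: float = 0.033,
    bead_density: float = 1.3,
    viscosity: float = 0.01,
    fluid_density: float = 1.0,
    vessel_radius_cm: float = 5.0,
) -> RotationScenario:
    """Rotating-wall-vessel microcarrier benchmark scenario.

    A 330 µm bead of density 1.3 g/cm³ in a 5 cm vessel spinning at
    35 rpm — the classic validation case in which a dense bead spirals
    slowly outward toward the wall with each rotation.
    """
    from .physics import FluidProps, ParticleProps, VesselGeometry, rpm_to_rad_per_s

    return RotationScenario(
        particle=ParticleProps(radius_a=bead_radius_cm, density_rho_p=bead_density),
        fluid=FluidProps(viscosity_mu=viscosity, density_rho_f=fluid_density),
        vessel=VesselGeometry(lumen_radius_R=vessel_radius_cm),
        omega=rpm_to_rad_per_s(speed_rpm),
    )


def replicate_microcarrier_case(
    config: Optional[SimConfig] = None,
    start_r_cm: float = 0.5,
    start_theta_rad: float = math.pi / 2.0,
    **scenario_kwargs,
) -> TrajectoryResult:
    """Run the microcarrier benchmark: bead starting at r = 0.5 cm, 90°.

    Unlike the cell-scale case, the bead's inertia is non-negligible
    (relaxation time ~0.04 s against a 1.7 s period), so its orbit is an
    outward exponential spiral: the orbit-averaged radius grows ~16 % per
    revolution until the bead meets the vessel wall after ~3.5 revolutions.
    """
    if config is None:
        config = SimConfig(max_revolutions=8)
    scenario = microcarrier_scenario(**scenario_kwargs)
    initial = TrajectoryState(r=start_r_cm, theta=start_theta_rad)
    return simulate_trajectory(initial, scenario, config)
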