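"""Equations of motion, full-ODE integration, and the overdamped oracle.

Two independent oracles back the integrator: the overdamped closed-form
circle (valid for cell-scale particles, relaxation time << period) and the
exact solution of the full linear system computed here by eigendecomposition
(valid in every regime, used for the inertial microcarrier case).
"""

import math

import numpy as np
import pytest

from rotaseed import (
    IntegrationError,
    RegimeError,
    SimConfig,
    SolverMode,
    TrajectoryState,
    equations_of_motion,
    microcarrier_scenario,
    overdamped_orbit,
    replicate_microcarrier_case,
    settling_velocity,
    simulate_trajectory,
)
from .conftest import START_RADII, cell_scenario


def exact_linear_path(scenario, r0, theta0, times):
    """Independent oracle: exact solution of the Cartesian linear ODE.

    With z = x + iy the system is M z'' + D z' + (m(1+Cv)w^2 - iDw) z =
    i(m - mp)g; solved by eigendecomposition, valid in every inertia regime.
    """
    m = scenario.displaced_mass
    mp = scenario.particle.mass_mp
    M = scenario.effective_mass
    Cv = scenario.particle.virtual_mass_Cv
    D = scenario.stokes_drag_coefficient
    om = scenario.omega
    g = scenario.gravity_g
    c0 = m * (1 + Cv) * om**2 - 1j * D * om
    zstar = 1j * (m - mp) * g / c0
    l1, l2 = np.roots([M, D, c0])
    z0 = r0 * np.exp(1j * theta0)
    v0 = 1j * om * z0  # co-rotating start
    A, B = np.linalg.solve([[1, 1], [l1, l2]], [z0 - zstar, v0])
    return zstar + A * np.exp(l1 * times) + B * np.exp(l2 * times)


class TestEquationsOfMotion:
    def test_neutral_buoyancy_corotating_fixed_point(self):
        scen = cell_scenario(24.0, density=1.0)  # rho_p = rho_f
        state = TrajectoryState(r=0.02, theta=1.0, v_r=0.0, theta_dot=scen.omega)
        dr, dth, dvr, dthd = equations_of_motion(state, scen)
        assert dvr == pytest.approx(0.0, abs=1e-18)
        assert dthd == pytest.approx(0.0, abs=1e-18)

    def test_corotating_at_top_of_lumen(self):
        # drag vanishes when co-rotating with v_r = 0, so the radial
        # acceleration is the pressure-gradient term plus radial gravity
        scen = cell_scenario(24.0)
        om = scen.omega
        state = TrajectoryState(r=0.02, theta=math.pi / 2, v_r=0.0, theta_dot=om)
        _, _, dvr, dthd = equations_of_motion(state, scen)
        m, mp, M = scen.displaced_mass, scen.particle.mass_mp, scen.effective_mass
        expected = 0.02 * om**2 + (-m * 1.5 * om**2 * 0.02 + (m - mp) * scen.gravity_g) / M
        assert dvr == pytest.approx(expected, rel=1e-12)
        # residual is float roundoff of cos(pi/2), not a physical term
        assert dthd == pytest.approx(0.0, abs=1e-12)

    def test_no_rotation_at_rest_gives_buoyant_gravity(self):
        scen = cell_scenario(0.0)
        state = TrajectoryState(r=0.01, theta=0.7, v_r=0.0, theta_dot=0.0)
        _, _, dvr, dthd = equations_of_motion(state, scen)
        accel = math.hypot(dvr, 0.01 * dthd)
        expected = abs(scen.delta_rho) * scen.particle.volume_Vp * scen.gravity_g / scen.effective_mass
        assert accel == pytest.approx(expected, rel=1e-12)

    def test_regular_at_axis(self):
        scen = cell_scenario(24.0)
        state = TrajectoryState(r=0.0, theta=0.3, v_r=0.0, theta_dot=0.0)
        derivs = equations_of_motion(state, scen)
        assert all(math.isfinite(d) for d in derivs)


class TestSimulateTrajectory:
    def test_contact_pattern_at_seeding_speed(self, start_angle_top):
        # at 24 rph only the outermost start reaches the wall
        scen = cell_scenario(24.0)
        outcomes = {}
        for r0 in START_RADII:
            res = simulate_trajectory(TrajectoryState(r=r0, theta=start_angle_top), scen)
            outcomes[r0] = res.contacted_wall
        assert outcomes == {0.001: False, 0.005: False, 0.01: False, 0.02: True}

    def test_contact_result_consistency(self, start_angle_top):
        scen = cell_scenario(24.0)
        res = simulate_trajectory(TrajectoryState(r=0.02, theta=start_angle_top), scen)
        assert res.contacted_wall
        assert res.contact_time_s is not None and res.contact_time_s > 0
        assert res.contact_angle_rad is not None
        # path ends on the wall, to solver tolerance, and never overshoots
        assert res.r_cm[-1] == pytest.approx(0.04, abs=1e-8)
        assert res.r_cm.max() <= 0.04 + 1e-8
        assert np.all(np.diff(res.time_s) > 0)

    def test_no_contact_leaves_no_contact_fields(self, start_angle_top):
        scen = cell_scenario(24.0)
        res = simulate_trajectory(TrajectoryState(r=0.01, theta=start_angle_top), scen)
        assert not res.contacted_wall
        assert res.contact_time_s is None and res.contact_angle_rad is None

    def test_neutral_buoyancy_circular_orbit(self, start_angle_top):
        scen = cell_scenario(24.0, density=1.0)
        res = simulate_trajectory(TrajectoryState(r=0.01, theta=start_angle_top), scen)
        assert not res.contacted_wall
        # constant radius to integration accuracy (fraction of a nanometre
        # per revolution on a 100 um orbit)
        assert np.abs(res.r_cm - 0.01).max() < 1e-7

    def test_closed_orbit_drift_below_tolerance(self, start_angle_top):
        # cells that miss the wall retrace the same orbit each revolution
        scen = cell_scenario(24.0)
        res = simulate_trajectory(TrajectoryState(r=0.01, theta=start_angle_top), scen)
        assert abs(res.orbit_drift_per_revolution_cm) < 1e-6

    def test_initial_radius_at_wall_rejected(self, start_angle_top):
        scen = cell_scenario(24.0)
        with pytest.raises(ValueError, match="contact radius"):
            simulate_trajectory(TrajectoryState(r=0.05, theta=start_angle_top), scen)

    def test_pure_settling_without_rotation(self, start_angle_top):
        # omega = 0 in overdamped mode: straight settling to the bottom
        scen = cell_scenario(0.0)
        cfg = SimConfig(solver_mode=SolverMode.OVERDAMPED)
        res = simulate_trajectory(TrajectoryState(r=0.02, theta=start_angle_top), scen, cfg)
        assert res.contacted_wall
        w = settling_velocity(scen.particle, scen.fluid, scen.gravity_g)
        assert res.contact_time_s == pytest.approx((0.02 + 0.04) / w, rel=1e-9)
        # contact at the bottom of the lumen
        assert res.contact_angle_rad == pytest.approx(3 * math.pi / 2, abs=1e-6)


class TestOverdampedOracle:
    @pytest.mark.parametrize("speed, r0", [(24.0, 0.001), (24.0, 0.005), (24.0, 0.01), (30.0, 0.02)])
    def test_full_ode_matches_closed_form(self, speed, r0, start_angle_top):
        scen = cell_scenario(speed)
        initial = TrajectoryState(r=r0, theta=start_angle_top)
        full = simulate_trajectory(initial, scen)
        od = overdamped_orbit(initial, scen)
        assert not full.contacted_wall and not od.contacted_wall
        dx = full.x_cm - od.x_cm
        dy = full.y_cm - od.y_cm
        assert np.hypot(dx, dy).max() < 0.01 * 0.04

    def test_contact_times_agree(self, start_angle_top):
        scen = cell_scenario(24.0)
        initial = TrajectoryState(r=0.02, theta=start_angle_top)
        full = simulate_trajectory(initial, scen)
        od = overdamped_orbit(initial, scen)
        assert full.contacted_wall and od.contacted_wall
        assert od.contact_time_s == pytest.approx(full.contact_time_s, rel=1e-3)

    def test_all_radii_contact_at_low_speed(self, start_angle_top):
        # at 15 rph every tested start reaches the wall within one revolution
        scen = cell_scenario(15.0)
        for r0 in START_RADII:
            od = overdamped_orbit(TrajectoryState(r=r0, theta=start_angle_top), scen)
            assert od.contacted_wall
            assert od.contact_time_s < 2 * math.pi / scen.omega

    def test_excursion_threshold_at_seeding_speed(self, start_angle_top):
        # max excursion sqrt(r0^2 + (w/omega)^2) + w/omega crosses 0.04 cm
        # only for the outermost start at 24 rph
        scen = cell_scenario(24.0)
        w = settling_velocity(scen.particle, scen.fluid, scen.gravity_g)
        c = w / scen.omega
        for r0 in START_RADII:
            od = overdamped_orbit(TrajectoryState(r=r0, theta=start_angle_top), scen)
            assert od.contacted_wall == (math.hypot(r0, c) + c >= 0.04)
        assert [r0 for r0 in START_RADII
                if math.hypot(r0, c) + c >= 0.04] == [0.02]

    def test_neutral_buoyancy_circle_about_axis(self, start_angle_top):
        scen = cell_scenario(24.0, density=1.0)
        od = overdamped_orbit(TrajectoryState(r=0.01, theta=start_angle_top), scen)
        assert np.abs(od.r_cm - 0.01).max() < 1e-12
        assert not od.contacted_wall

    def test_regime_error_for_inertial_bead(self):
        scen = microcarrier_scenario()
        with pytest.raises(RegimeError):
            overdamped_orbit(TrajectoryState(r=0.5, theta=math.pi / 2), scen)


class TestMicrocarrierBenchmark:
    def test_outward_spiral_until_wall(self):
        res = replicate_microcarrier_case()
        means = res.revolution_mean_radii_cm
        # the dense bead spirals outward: every completed revolution sits
        # farther from the axis, until the wall stops it
        assert res.contacted_wall
        assert means.size >= 3
        assert np.all(np.diff(means) > 0)
        assert res.orbit_drift_per_revolution_cm > 0.1

    def test_matches_exact_linear_solution(self):
        # inertial regime: validate against the eigendecomposition oracle
        res = replicate_microcarrier_case()
        scen = res.scenario
        z = exact_linear_path(scen, 0.5, math.pi / 2, res.time_s)
        err = np.hypot(res.x_cm - z.real, res.y_cm - z.imag)
        assert err.max() < 1e-4  # cm, on a 5 cm vessel

    def test_drift_dwarfs_cell_drift(self, start_angle_top):
        cell = simulate_trajectory(
            TrajectoryState(r=0.01, theta=start_angle_top), cell_scenario(24.0)
        )
        bead = replicate_microcarrier_case()
        ratio = bead.orbit_drift_per_revolution_cm / abs(cell.orbit_drift_per_revolution_cm)
        assert ratio > 1e3

    def test_light_bead_drifts_inward(self):
        # reversing the density difference reverses the drift direction
        res = replicate_microcarrier_case(bead_density=0.7)
        means = res.revolution_mean_radii_cm
        assert means.size >= 2
        assert np.all(np.diff(means) < 0)


class TestDensityEffect:
    def test_denser_cell_larger_orbit(self, start_angle_top):
        # raising rho_p enlarges the orbit's horizontal offset w/omega;
        # at a fast confined-trajectory speed both densities stay suspended
        # and the full circle is swept, so the offset is the x-midrange
        lo = simulate_trajectory(
            TrajectoryState(r=0.005, theta=start_angle_top), cell_scenario(360.0, density=1.05)
        )
        hi = simulate_trajectory(
            TrajectoryState(r=0.005, theta=start_angle_top), cell_scenario(360.0, density=1.2)
        )
        assert not lo.contacted_wall and not hi.contacted_wall
        offset_lo = (lo.x_cm.max() + lo.x_cm.min()) / 2
        offset_hi = (hi.x_cm.max() + hi.x_cm.min()) / 2
        assert offset_hi > offset_lo > 0

    def test_contact_monotone_in_start_radius(self, start_angle_top):
        # if a start radius contacts, every larger tested radius contacts too
        scen = cell_scenario(26.0)
        contacted = [
            simulate_trajectory(TrajectoryState(r=r0, theta=start_angle_top), scen).contacted_wall
            for r0 in START_RADII
        ]
        first = contacted.index(True) if True in contacted else len(contacted)
        assert all(contacted[first:])
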