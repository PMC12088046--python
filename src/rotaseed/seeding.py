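"""Wall-contact mapping across rotation speeds and the adherent-cell force balance.

Sweeps of the trajectory simulator over initial radial positions and
rotation speeds identify which seeding conditions bring settling cells into
contact with the lumen wall, and the largest rotation speed that still
permits contact.  For cells that have just adhered, the module evaluates
the rotational drag and the angle-dependent gravitational load against
literature detachment thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .physics import (
    DYN_TO_N,
    GRAVITY_CGS,
    ParticleProps,
    RotationScenario,
    rph_to_rad_per_s,
)
from .trajectory import (
    IntegrationError,
    SimConfig,
    TrajectoryState,
    contact_radius,
    simulate_trajectory,
)

__all__ = [
    "ContactMap",
    "DepositionSummary",
    "ForceReport",
    "DETACHMENT_THRESHOLDS_N",
    "contact_map",
    "max_contact_speed",
    "deposition_angles",
    "adherent_drag_force",
    "gravitational_force",
    "adhesion_stability_report",
]

#: Literature detachment-force thresholds for newly adherent endothelial
#: cells, keyed by the wall shear stress that generates them.  Stored as
#: named constants (the underlying cell-geometry model is not re-derived
#: here); a rotational drag below the lower threshold is considered safe.
DETACHMENT_THRESHOLDS_N: dict[str, float] = {
    "shear_0.01_Pa": 1.57e-11,
    "shear_0.1_Pa": 1.57e-10,
}


@dataclass
class ContactMap:
    """Grid of wall-contact outcomes over (rotation speed × start radius).

    Matrices are indexed [speed, radius]; times and angles are NaN where no
    contact occurred, and ``failed`` marks grid cells whose integration
    did not converge (recorded, never fatal).
    """

    speeds_rph: np.ndarray
    start_radii_cm: np.ndarray
    start_angle_rad: float
    contacted: np.ndarray
    contact_time_s: np.ndarray
    contact_angle_rad: np.ndarray
    failed: np.ndarray
    failure_messages: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.speeds_rph), len(self.start_radii_cm))
        for name in ("contacted", "contact_time_s", "contact_angle_rad", "failed"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")

    def contacting_radii(self, speed_rph: float) -> np.ndarray:
        """Start radii that reached the wall at the given speed."""
        i = int(np.flatnonzero(np.isclose(self.speeds_rph, speed_rph))[0])
        return self.start_radii_cm[self.contacted[i]]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, s in enumerate(self.speeds_rph):
            for j, r0 in enumerate(self.start_radii_cm):
                rows.append(
                    {
                        "speed_rph": s,
                        "r0_cm": r0,
                        "contacted": bool(self.contacted[i, j]),
                        "contact_time_s": self.contact_time_s[i, j],
                        "contact_angle_rad": self.contact_angle_rad[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class DepositionSummary:
    """Angular distribution of wall-contact points for an ensemble of starts.

    ``circular_variance`` is 1 − |mean resultant vector| of the contact
    angles: 0 for perfectly focused deposition, →1 for uniform coverage.
    ``empty`` flags an ensemble in which nothing contacted the wall.
    """

    bin_edges_rad: np.ndarray
    counts: np.ndarray
    n_contacting: int
    n_total: int
    circular_variance: float
    empty: bool

    @property
    def normalized_counts(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)


@dataclass
class ForceReport:
    """Force balance on a newly adherent cell at the lumen wall.

    Forces in newtons.  ``safe`` compares the rotational drag against each
    detachment threshold (drag strictly below threshold → safe).
    """

    drag_force_N: float
    gravity_force_max_N: float
    gravity_theta_rad: np.ndarray
    gravity_force_N: np.ndarray
    thresholds_N: dict[str, float]
    safe: dict[str, bool]
    speed_rph: float

    def as_dict(self) -> dict:
        return {
            "speed_rph": self.speed_rph,
            "drag_force_N": self.drag_force_N,
            "gravity_force_max_N": self.gravity_force_max_N,
            "thresholds_N": dict(self.thresholds_N),
            "safe": dict(self.safe),
            "gravity_vs_angle": {
                "theta_rad": self.gravity_theta_rad.tolist(),
                "force_N": self.gravity_force_N.tolist(),
            },
        }


def contact_map(
    scenario_base: RotationScenario,
    speeds_rph: Sequence[float],
    start_radii_cm: Sequence[float],
    start_angle_rad: float = math.pi / 2.0,
    config: SimConfig = SimConfig(),
) -> ContactMap:
    """Simulate every (speed, start radius) pair and record contact outcomes.

    Runs one full trajectory integration per grid cell; entirely
    deterministic.  Integration failures are recorded per cell.
    """
    speeds = np.asarray(list(speeds_rph), dtype=float)
    radii = np.asarray(list(start_radii_cm), dtype=float)
    if speeds.size == 0 or radii.size == 0:
        raise ValueError("speeds and start radii must be non-empty")
    r_c = contact_radius(scenario_base, config.contact_criterion)
    if np.any(radii >= r_c):
        raise ValueError(f"all start radii must be < contact radius {r_c}")

    shape = (speeds.size, radii.size)
    contacted = np.zeros(shape, dtype=bool)
    t_contact = np.full(shape, np.nan)
    a_contact = np.full(shape, np.nan)
    failed = np.zeros(shape, dtype=bool)
    messages: dict[tuple[int, int], str] = {}

    for i, s in enumerate(speeds):
        scen = scenario_base.with_speed_rph(float(s))
        for j, r0 in enumerate(radii):
            initial = TrajectoryState(r=float(r0), theta=start_angle_rad)
            try:
                res = simulate_trajectory(initial, scen, config)
            except IntegrationError as exc:
                failed[i, j] = True
                messages[(i, j)] = str(exc)
                continue
            contacted[i, j] = res.contacted_wall
            if res.contacted_wall:
                t_contact[i, j] = res.contact_time_s
                a_contact[i, j] = res.contact_angle_rad

    return ContactMap(
        speeds_rph=speeds,
        start_radii_cm=radii,
        start_angle_rad=start_angle_rad,
        contacted=contacted,
        contact_time_s=t_contact,
        contact_angle_rad=a_contact,
        failed=failed,
        failure_messages=messages,
    )


def max_contact_speed(
    scenario_base: RotationScenario,
    start_radii_cm: Sequence[float],
    speed_range_rph: Iterable[int] = range(15, 36),
    start_angle_rad: float = math.pi / 2.0,
    config: SimConfig = SimConfig(),
) -> Optional[int]:
    """Largest integer speed (rph) at which any start radius reaches the wall.

    Sweeps the integer speeds in ``speed_range_rph`` and returns the
    largest one with at least one contacting start radius, or ``None``
    if no speed in the range produces contact.
    """
    speeds = sorted(int(s) for s in speed_range_rph)
    if not speeds:
        raise ValueError("speed range must be non-empty")
    cmap = contact_map(scenario_base, speeds, start_radii_cm, start_angle_rad, config)
    any_contact = cmap.contacted.any(axis=1)
    if not any_contact.any():
        return None
    return int(cmap.speeds_rph[any_contact].max())


def deposition_angles(
    scenario_base: RotationScenario,
    starts: Sequence[TrajectoryState],
    config: SimConfig = SimConfig(),
    n_bins: int = 36,
) -> DepositionSummary:
    """Histogram of wall-contact angles for an ensemble of initial positions.

    Bins contact angles over [0, 2π) and reports the circular variance of
    the deposition pattern — the quantity of interest for judging how
    uniformly a given rotation speed distributes cells around the lumen.
    """
    if len(starts) == 0:
        raise ValueError("ensemble of starts must be non-empty")
    angles = []
    for st in starts:
        res = simulate_trajectory(st, scenario_base, config)
        if res.contacted_wall:
            angles.append(res.contact_angle_rad % (2.0 * math.pi))
    edges = np.linspace(0.0, 2.0 * math.pi, n_bins + 1)
    if not angles:
        return DepositionSummary(
            bin_edges_rad=edges,
            counts=np.zeros(n_bins, dtype=int),
            n_contacting=0,
            n_total=len(starts),
            circular_variance=math.nan,
            empty=True,
        )
    arr = np.asarray(angles)
    counts, _ = np.histogram(arr, bins=edges)
    resultant = abs(np.exp(1j * arr).mean())
    return DepositionSummary(
        bin_edges_rad=edges,
        counts=counts,
        n_contacting=len(angles),
        n_total=len(starts),
        circular_variance=1.0 - resultant,
        empty=False,
    )


def adherent_drag_force(scenario: RotationScenario) -> float:
    """Rotational drag on a cell adhered at the lumen wall, in newtons.

    F = 6πμ·a·(Rω): Stokes drag on a sphere held stationary where the
    rotating fluid moves at the wall speed Rω.  Computed in dynes and
    converted (1 dyn = 1e-5 N).
    """
    mu = scenario.fluid.viscosity_mu
    a = scenario.particle.radius_a
    R = scenario.vessel.lumen_radius_R
    f_dyn = 6.0 * math.pi * mu * a * R * scenario.omega
    return f_dyn * DYN_TO_N


def gravitational_force(
    particle: ParticleProps, theta_rad: float, g: float = GRAVITY_CGS
) -> float:
    """Gravitational load on an adherent cell at lumen angle θ, in newtons.

    F = mₚ·g·cos(θ/2) with θ measured from the top of the lumen, where the
    load is maximal (θ = 0 → F = mₚg); at θ = π the cos(θ/2) factor
    vanishes.  Uses the full cell mass (no buoyancy correction): the
    relevant load on the adhesion is the cell's own weight.
    """
    if not 0.0 <= theta_rad < 2.0 * math.pi + 1e-12:
        raise ValueError(f"theta_rad must be in [0, 2*pi), got {theta_rad}")
    f_dyn = particle.mass_mp * g * math.cos(theta_rad / 2.0)
    return f_dyn * DYN_TO_N


def adhesion_stability_report(
    scenario: RotationScenario, n_theta: int = 181
) -> ForceReport:
    """Compare drag and gravity on an adherent cell against detachment thresholds.

    ``safe[threshold]`` is True iff the rotational drag stays strictly
    below that threshold; at seeding speeds up to ~29 rph the drag
    (~2e-12 N at 24 rph) is an order of magnitude below the lowest
    detachment threshold.
    """
    drag = adherent_drag_force(scenario)
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    grav = np.array([gravitational_force(scenario.particle, t, scenario.gravity_g) for t in theta])
    # |cos(theta/2)| is maximal at theta=0; the signed value can be negative
    # past theta=pi (load pulling along the wall), so report magnitude peak
    g_max = gravitational_force(scenario.particle, 0.0, scenario.gravity_g)
    from .physics import rad_per_s_to_rph

    return ForceReport(
        drag_force_N=drag,
        gravity_force_max_N=g_max,
        gravity_theta_rad=theta,
        gravity_force_N=grav,
        thresholds_N=dict(DETACHMENT_THRESHOLDS_N),
        safe={name: drag < thr for name, thr in DETACHMENT_THRESHOLDS_N.items()},
        speed_rph=rad_per_s_to_rph(scenario.omega),
    )
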