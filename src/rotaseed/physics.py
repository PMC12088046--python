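"""Domain types, unit conventions, and lumen geometry for rotational seeding.

All quantities are held internally in CGS units (cm, g, s, dyn): every
parameter of the seeding problem — viscosities in g/(cm·s), densities in
g/cm³, lengths in cm — is naturally expressed in CGS, and keeping a single
internal unit system avoids silent conversion bugs.  Forces are converted
to newtons only at reporting boundaries (1 dyn = 1e-5 N); wall shear
stresses to pascal (1 dyn/cm² = 0.1 Pa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "GRAVITY_CGS",
    "DYN_TO_N",
    "DYN_PER_CM2_TO_PA",
    "ParticleProps",
    "FluidProps",
    "VesselGeometry",
    "RotationScenario",
    "SeedingDose",
    "rph_to_rad_per_s",
    "rad_per_s_to_rph",
    "rpm_to_rad_per_s",
    "period_min_to_rph",
    "reynolds_number",
    "settling_velocity",
    "luminal_surface_area",
    "luminal_volume",
    "seeding_dose",
]

#: standard gravity in CGS (cm/s²)
GRAVITY_CGS: float = 980.0
#: 1 dyn = 1e-5 N
DYN_TO_N: float = 1.0e-5
#: 1 dyn/cm² = 0.1 Pa
DYN_PER_CM2_TO_PA: float = 0.1


@dataclass(frozen=True)
class ParticleProps:
    """A suspended spherical particle (cell or microcarrier bead).

    Parameters
    ----------
    radius_a:
        Particle radius ``a`` in cm (an endothelial cell is ~7.5e-4 cm).
    density_rho_p:
        Particle mass density in g/cm³.
    virtual_mass_Cv:
        Virtual (added) mass coefficient; 0.5 for a sphere.  Accounts for
        the fluid that must be accelerated along with the particle.
    """

    radius_a: float
    density_rho_p: float
    virtual_mass_Cv: float = 0.5

    def __post_init__(self) -> None:
        if self.radius_a <= 0:
            raise ValueError(f"radius_a must be > 0, got {self.radius_a}")
        if self.density_rho_p <= 0:
            raise ValueError(f"density_rho_p must be > 0, got {self.density_rho_p}")
        if self.virtual_mass_Cv < 0:
            raise ValueError(f"virtual_mass_Cv must be >= 0, got {self.virtual_mass_Cv}")

    @property
    def volume_Vp(self) -> float:
        """Particle volume (4/3)πa³ in cm³."""
        return (4.0 / 3.0) * math.pi * self.radius_a**3

    @property
    def mass_mp(self) -> float:
        """Particle mass ρₚ·Vₚ in g."""
        return self.density_rho_p * self.volume_Vp


@dataclass(frozen=True)
class FluidProps:
    """Culture medium properties: dynamic viscosity (g/(cm·s)) and density (g/cm³).

    The default density of 1.00 g/cm³ paired with a cell density of
    1.05 g/cm³ gives the ~0.05 g/cm³ density difference that drives
    settling of endothelial cells in medium at 37 °C.
    """

    viscosity_mu: float
    density_rho_f: float = 1.0

    def __post_init__(self) -> None:
        if self.viscosity_mu <= 0:
            raise ValueError(f"viscosity_mu must be > 0, got {self.viscosity_mu}")
        if self.density_rho_f <= 0:
            raise ValueError(f"density_rho_f must be > 0, got {self.density_rho_f}")


@dataclass(frozen=True)
class VesselGeometry:
    """Cylindrical lumen geometry: inner radius and axial length, in cm."""

    lumen_radius_R: float
    length_L: float = 0.0

    def __post_init__(self) -> None:
        if self.lumen_radius_R <= 0:
            raise ValueError(f"lumen_radius_R must be > 0, got {self.lumen_radius_R}")
        if self.length_L < 0:
            raise ValueError(f"length_L must be >= 0, got {self.length_L}")


@dataclass(frozen=True)
class RotationScenario:
    """Bundle of particle, fluid, vessel geometry, and rotation speed.

    The fluid inside the slowly rotating lumen is in solid-body rotation
    (v_θ = rω); the scenario carries everything needed to evaluate the
    forces on a suspended particle.

    Attributes
    ----------
    omega:
        Angular speed of the vessel about its axis, rad/s (counter-clockwise).
    gravity_g:
        Gravitational acceleration, cm/s² (default 980).
    """

    particle: ParticleProps
    fluid: FluidProps
    vessel: VesselGeometry
    omega: float
    gravity_g: float = GRAVITY_CGS

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if self.gravity_g < 0:
            raise ValueError(f"gravity_g must be >= 0, got {self.gravity_g}")

    @property
    def displaced_mass(self) -> float:
        """Mass of fluid displaced by the particle, m = ρ_f·Vₚ (g)."""
        return self.fluid.density_rho_f * self.particle.volume_Vp

    @property
    def effective_mass(self) -> float:
        """Effective inertia M = mₚ + Cᵥ·m (g), including virtual mass."""
        return self.particle.mass_mp + self.particle.virtual_mass_Cv * self.displaced_mass

    @property
    def delta_rho(self) -> float:
        """Density difference Δρ = ρₚ − ρ_f (g/cm³); positive for a settling particle."""
        return self.particle.density_rho_p - self.fluid.density_rho_f

    @property
    def stokes_drag_coefficient(self) -> float:
        """Stokes drag coefficient 6πμa (g/s); drag force = 6πμa · slip velocity."""
        return 6.0 * math.pi * self.fluid.viscosity_mu * self.particle.radius_a

    @property
    def relaxation_time(self) -> float:
        """Momentum relaxation time M/(6πμa) in s.

        For a 7.5 µm cell in medium this is ~2e-5 s, utterly negligible
        against a ~150 s rotation period — the basis of the overdamped
        closed-form orbit.
        """
        return self.effective_mass / self.stokes_drag_coefficient

    def with_omega(self, omega: float) -> "RotationScenario":
        """Copy of this scenario at a different angular speed (rad/s)."""
        return replace(self, omega=omega)

    def with_speed_rph(self, speed_rph: float) -> "RotationScenario":
        """Copy of this scenario at a rotation speed given in rev/h."""
        return replace(self, omega=rph_to_rad_per_s(speed_rph))


@dataclass(frozen=True)
class SeedingDose:
    """Cell dose for luminal injection: total count and suspension concentration."""

    cell_count: float
    concentration_per_ml: float


def rph_to_rad_per_s(speed_rph: float) -> float:
    """Convert revolutions per hour to rad/s."""
    if speed_rph < 0:
        raise ValueError(f"speed_rph must be >= 0, got {speed_rph}")
    return speed_rph * 2.0 * math.pi / 3600.0


def rad_per_s_to_rph(omega: float) -> float:
    """Convert rad/s to revolutions per hour (inverse of :func:`rph_to_rad_per_s`)."""
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    return omega * 3600.0 / (2.0 * math.pi)


def rpm_to_rad_per_s(speed_rpm: float) -> float:
    """Convert revolutions per minute to rad/s."""
    if speed_rpm < 0:
        raise ValueError(f"speed_rpm must be >= 0, got {speed_rpm}")
    return speed_rpm * 2.0 * math.pi / 60.0


def period_min_to_rph(period_min: float) -> float:
    """Rotation speed in rev/h for a given rotation period in minutes.

    A measured period of one rotation every 2.5 min corresponds to 24 rph.
    """
    if period_min <= 0:
        raise ValueError(f"period_min must be > 0, got {period_min}")
    return 60.0 / period_min


def reynolds_number(scenario: RotationScenario) -> float:
    """Rotational Reynolds number of the lumen flow.

    Uses the wall speed ωR as characteristic velocity and the lumen
    diameter 2R as characteristic length:

        Re = ρ_f · (ωR) · (2R) / μ

    For the endothelial seeding condition (24 rph, R = 0.04 cm, medium at
    37 °C) this evaluates to ~0.016, firmly in the laminar solid-body
    rotation regime.
    """
    mu = scenario.fluid.viscosity_mu
    if mu <= 0:
        raise ValueError("viscosity must be > 0")
    R = scenario.vessel.lumen_radius_R
    return scenario.fluid.density_rho_f * (scenario.omega * R) * (2.0 * R) / mu


def settling_velocity(
    particle: ParticleProps, fluid: FluidProps, g: float = GRAVITY_CGS
) -> float:
    """Stokes terminal settling velocity w = 2Δρ·g·a²/(9μ), cm/s, downward-positive.

    Obtained by balancing net weight ΔρVₚg against Stokes drag 6πμaw.
    Negative for a particle lighter than the fluid (it rises).
    """
    delta_rho = particle.density_rho_p - fluid.density_rho_f
    return 2.0 * delta_rho * g * particle.radius_a**2 / (9.0 * fluid.viscosity_mu)


def luminal_surface_area(vessel: VesselGeometry) -> float:
    """Inner luminal (lateral) surface area 2πRL in cm²."""
    return 2.0 * math.pi * vessel.lumen_radius_R * vessel.length_L


def luminal_volume(vessel: VesselGeometry) -> float:
    """Lumen volume πR²L in cm³."""
    return math.pi * vessel.lumen_radius_R**2 * vessel.length_L


def seeding_dose(density_per_cm2: float, vessel: VesselGeometry) -> SeedingDose:
    """Cell count and injection concentration for a target surface density.

    ``count = density · 2πRL``; the concentration is the count divided by
    the lumen volume (cells/mL, since 1 cm³ = 1 mL), i.e. the suspension
    concentration needed so that a lumen-filling injection carries exactly
    the target dose.
    """
    if density_per_cm2 < 0:
        raise ValueError(f"density_per_cm2 must be >= 0, got {density_per_cm2}")
    count = density_per_cm2 * luminal_surface_area(vessel)
    vol = luminal_volume(vessel)
    conc = count / vol if vol > 0 else math.nan
    return SeedingDose(cell_count=count, concentration_per_ml=conc)
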