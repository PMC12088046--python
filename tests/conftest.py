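import math

import pytest
from hypothesis import HealthCheck, settings

from rotaseed import (
    FluidProps,
    ParticleProps,
    RotationScenario,
    VesselGeometry,
    rph_to_rad_per_s,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: start radii examined in the rotation-speed study (cm)
START_RADII = (0.001, 0.005, 0.01, 0.02)


def cell_scenario(speed_rph: float = 24.0, density: float = 1.05) -> RotationScenario:
    """Endothelial cell in the TEBV lumen at the given rotation speed."""
    return RotationScenario(
        particle=ParticleProps(radius_a=7.5e-4, density_rho_p=density, virtual_mass_Cv=0.5),
        fluid=FluidProps(viscosity_mu=0.0085, density_rho_f=1.0),
        vessel=VesselGeometry(lumen_radius_R=0.04, length_L=1.0),
        omega=rph_to_rad_per_s(speed_rph),
    )


@pytest.fixture
def cell_24rph() -> RotationScenario:
    return cell_scenario(24.0)


@pytest.fixture
def start_angle_top() -> float:
    """Start angle at the top of the lumen, directly above the axis."""
    return math.pi / 2.0
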