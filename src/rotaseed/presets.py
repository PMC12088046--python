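"""Named parameter presets and YAML config handling.

Presets are flat key–value YAML files shipped with the package; any file
with the same keys can be passed in their place.  Keys carry their units in
the name (``*_cm``, ``*_g_cm3``, ``speed_rph`` …) so configs are
self-describing.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .physics import FluidProps, ParticleProps, RotationScenario, VesselGeometry, rph_to_rad_per_s

__all__ = ["PRESET_NAMES", "load_config", "scenario_from_config", "load_scenario"]

PRESET_NAMES = ("tebv-cell", "microcarrier-rwv", "tebv-speed-sweep", "perfusion-ramp")


def load_config(source: Union[str, Path]) -> dict:
    """Load a flat-key config from a preset name or a YAML file path."""
    name = str(source)
    if name in PRESET_NAMES:
        text = resources.files("rotaseed").joinpath("data", f"{name}.yaml").read_text()
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"{source!r} is neither a preset ({', '.join(PRESET_NAMES)}) nor an existing file"
            )
        text = path.read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {source!r} must be a flat key-value mapping")
    return cfg


def scenario_from_config(cfg: dict, speed_rph: float | None = None) -> RotationScenario:
    """Build a :class:`RotationScenario` from flat config keys.

    ``speed_rph`` overrides the config's rotation speed when given.
    """
    try:
        particle = ParticleProps(
            radius_a=float(cfg["particle_radius_cm"]),
            density_rho_p=float(cfg["particle_density_g_cm3"]),
            virtual_mass_Cv=float(cfg.get("virtual_mass_coefficient", 0.5)),
        )
        fluid = FluidProps(
            viscosity_mu=float(cfg["fluid_viscosity_g_cm_s"]),
            density_rho_f=float(cfg.get("fluid_density_g_cm3", 1.0)),
        )
        vessel = VesselGeometry(
            lumen_radius_R=float(cfg["lumen_radius_cm"]),
            length_L=float(cfg.get("vessel_length_cm", 0.0)),
        )
    except KeyError as exc:
        raise KeyError(f"config is missing required key {exc.args[0]!r}") from None
    speed = speed_rph if speed_rph is not None else float(cfg.get("speed_rph", 0.0))
    return RotationScenario(
        particle=particle,
        fluid=fluid,
        vessel=vessel,
        omega=rph_to_rad_per_s(speed),
        gravity_g=float(cfg.get("gravity_cm_s2", 980.0)),
    )


def load_scenario(source: Union[str, Path], speed_rph: float | None = None) -> RotationScenario:
    """Shorthand: load a config and build its scenario in one call."""
    return scenario_from_config(load_config(source), speed_rph=speed_rph)
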