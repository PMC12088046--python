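"""Wall-shear-stress / flow-rate conversion and perfusion conditioning schedules.

After seeding, the endothelialized lumen is conditioned by luminal flow.
Steady laminar flow in a cylindrical conduit exerts the Poiseuille wall
shear stress

    τ = 4μQ / (πR³)

(τ in dyn/cm² for CGS inputs; reported in Pa, 1 dyn/cm² = 0.1 Pa).  Two
conditioning schemes are supported: a rapid start, which jumps straight to
the target stress, and gradual ramping, which raises the stress in steps so
newly adherent cells can strengthen their adhesion before full flow.

The nominal experimental pairing of 0.5 mL/min per vessel with 0.4 Pa is
shipped as a named preset; with nominal medium viscosity (0.0085 g/(cm·s))
and lumen radius (0.04 cm) the Poiseuille value at 0.5 mL/min is ~0.14 Pa,
so the preset preserves the pairing without asserting which effective
viscosity or radius underlies it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .physics import DYN_PER_CM2_TO_PA

__all__ = [
    "PerfusionParams",
    "RampMode",
    "RampStep",
    "RampSchedule",
    "wall_shear_stress",
    "flow_rate_for_stress",
    "ramp_schedule",
    "percent_circumferential_coverage",
]

_ML_PER_MIN_TO_CM3_PER_S = 1.0 / 60.0
# tracing tolerance: covered lengths may overshoot the perimeter by 0.5 %
_COVERAGE_TOLERANCE = 0.005


@dataclass(frozen=True)
class PerfusionParams:
    """Medium viscosity (g/(cm·s)), lumen radius (cm), vessels per pump line."""

    medium_viscosity: float = 0.0085
    lumen_radius: float = 0.04
    n_vessels: int = 1

    def __post_init__(self) -> None:
        if self.medium_viscosity <= 0:
            raise ValueError("medium_viscosity must be > 0")
        if self.lumen_radius <= 0:
            raise ValueError("lumen_radius must be > 0")
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")


class RampMode(enum.Enum):
    RAPID_START = "rapid_start"
    GRADUAL_RAMPING = "gradual_ramping"


@dataclass(frozen=True)
class RampStep:
    """One pump setting: time offset (min), wall shear stress (Pa), flow (mL/min/vessel)."""

    time_min: float
    shear_stress_pa: float
    flow_rate_ml_min: float


@dataclass(frozen=True)
class RampSchedule:
    """Ordered pump command table for one conditioning run."""

    steps: tuple[RampStep, ...]
    mode: RampMode
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        times = [s.time_min for s in self.steps]
        if times and times[0] != 0.0:
            raise ValueError("schedule must start at t=0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("step times must be strictly increasing")
        if any(s.shear_stress_pa < 0 for s in self.steps):
            raise ValueError("stresses must be non-negative")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_min": [s.time_min for s in self.steps],
                "tau_Pa": [s.shear_stress_pa for s in self.steps],
                "Q_mL_min": [s.flow_rate_ml_min for s in self.steps],
            }
        )


def wall_shear_stress(flow_rate_ml_min: float, params: PerfusionParams = PerfusionParams()) -> float:
    """Poiseuille wall shear stress τ = 4μQ/(πR³) in Pa, per vessel flow rate in mL/min."""
    if flow_rate_ml_min < 0:
        raise ValueError("flow_rate must be >= 0")
    Q = flow_rate_ml_min * _ML_PER_MIN_TO_CM3_PER_S
    tau_dyn = 4.0 * params.medium_viscosity * Q / (math.pi * params.lumen_radius**3)
    return tau_dyn * DYN_PER_CM2_TO_PA


def flow_rate_for_stress(stress_pa: float, params: PerfusionParams = PerfusionParams()) -> float:
    """Per-vessel flow rate (mL/min) producing a given wall shear stress (Pa).

    Exact inverse of :func:`wall_shear_stress`.
    """
    if stress_pa < 0:
        raise ValueError("stress must be >= 0")
    tau_dyn = stress_pa / DYN_PER_CM2_TO_PA
    Q = tau_dyn * math.pi * params.lumen_radius**3 / (4.0 * params.medium_viscosity)
    return Q / _ML_PER_MIN_TO_CM3_PER_S


def ramp_schedule(
    target_stress_pa: float = 0.4,
    start_stress_pa: float = 0.04,
    total_duration_min: float = 180.0,
    step_interval_min: float = 60.0,
    mode: RampMode = RampMode.GRADUAL_RAMPING,
    params: PerfusionParams = PerfusionParams(),
    interpolation: str = "linear",
) -> RampSchedule:
    """Build a perfusion conditioning schedule.

    Rapid start: a single step straight to the target stress at t = 0.
    Gradual ramping: steps at 0, Δt, 2Δt, …, total duration, with stresses
    interpolated from start to target (linear in stress by default,
    ``interpolation="geometric"`` for equal ratios); the first step is
    exactly the start stress and the last exactly the target.  The default
    arguments reproduce the 0.04 → 0.4 Pa ramp over 3 h in 60-min steps.
    """
    if start_stress_pa < 0 or target_stress_pa < start_stress_pa:
        raise ValueError("need target >= start >= 0")
    if mode is RampMode.RAPID_START or total_duration_min == 0:
        steps = (
            RampStep(0.0, target_stress_pa, flow_rate_for_stress(target_stress_pa, params)),
        )
        return RampSchedule(steps=steps, mode=mode, interpolation=interpolation)

    if step_interval_min <= 0:
        raise ValueError("step_interval_min must be > 0")
    n_steps_f = total_duration_min / step_interval_min
    n_steps = round(n_steps_f)
    if not math.isclose(n_steps_f, n_steps, rel_tol=0, abs_tol=1e-9):
        raise ValueError(
            f"step interval {step_interval_min} min does not divide total duration "
            f"{total_duration_min} min"
        )
    times = np.arange(n_steps + 1) * step_interval_min
    if interpolation == "linear":
        stresses = np.linspace(start_stress_pa, target_stress_pa, n_steps + 1)
    elif interpolation == "geometric":
        if start_stress_pa <= 0:
            raise ValueError("geometric interpolation requires start stress > 0")
        stresses = np.geomspace(start_stress_pa, target_stress_pa, n_steps + 1)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    stresses[-1] = target_stress_pa  # exact endpoint regardless of rounding
    steps = tuple(
        RampStep(float(t), float(tau), flow_rate_for_stress(float(tau), params))
        for t, tau in zip(times, stresses)
    )
    return RampSchedule(steps=steps, mode=mode, interpolation=interpolation)


def percent_circumferential_coverage(
    covered_lengths: Sequence[float], perimeter: float
) -> float:
    """Percent of the lumen cross-section perimeter covered by cells.

    100 · Σ(covered arc lengths) / perimeter, any consistent length unit.
    Traced covered lengths may overshoot the perimeter by up to 0.5 %
    (tracing error); the result is then clipped to 100.  A larger
    overshoot indicates inconsistent measurements and raises.
    """
    if perimeter <= 0:
        raise ValueError("perimeter must be > 0")
    lengths = [float(x) for x in covered_lengths]
    if any(x < 0 for x in lengths):
        raise ValueError("covered lengths must be >= 0")
    total = sum(lengths)
    if total > perimeter * (1.0 + _COVERAGE_TOLERANCE):
        raise ValueError(
            f"covered length {total} exceeds perimeter {perimeter} beyond tracing tolerance"
        )
    return min(100.0 * total / perimeter, 100.0)
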