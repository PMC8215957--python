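"""Loading inputs: triangular plate-velocity pulses, factorial under-body
blast (UBB) sweeps and pendulum initial conditions.

A UBB event is represented at the loading-plate level: the plate velocity
rises linearly to a peak and falls linearly back to rest (triangular pulse),
parameterized by peak velocity and time to peak.  Severity sweeps are full
factorial grids over those two parameters.  Pendulum validation tests are
parameterized by impactor velocity, impactor mass and the ballast mass at
the proximal tibia.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .signals import Signal

__all__ = [
    "PulseSpec",
    "LoadingGrid",
    "PendulumSpec",
    "triangular_pulse",
    "build_grid",
    "pendulum_conditions",
    "default_ubb_grid",
    "load_grid",
    "load_pendulum_modalities",
]


@dataclass(frozen=True)
class PulseSpec:
    """Triangular plate-velocity pulse.

    Rise linearly from 0 to ``peak_velocity`` (m/s) over ``time_to_peak``
    (s), fall linearly to 0 over ``fall_time`` (defaults to a symmetric
    triangle), then remain at rest until ``total_duration``.
    """

    peak_velocity: float
    time_to_peak: float
    fall_time: float | None = None
    total_duration: float | None = None

    def __post_init__(self) -> None:
        if self.peak_velocity < 0:
            raise ValueError("peak_velocity must be >= 0")
        if self.time_to_peak <= 0:
            raise ValueError("time_to_peak must be positive")
        if self.fall_time is None:
            object.__setattr__(self, "fall_time", self.time_to_peak)
        if self.fall_time < 0:
            raise ValueError("fall_time must be >= 0")
        if self.total_duration is None:
            object.__setattr__(self, "total_duration",
                               self.time_to_peak + self.fall_time)
        if self.total_duration < self.time_to_peak + self.fall_time - 1e-15:
            raise ValueError("total_duration shorter than the pulse itself")


@dataclass(frozen=True)
class LoadingGrid:
    """Factorial sweep levels: peak velocities (m/s) x times to peak (s)."""

    peak_velocities: tuple[float, ...]
    times_to_peak: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, levels in (("peak_velocities", self.peak_velocities),
                             ("times_to_peak", self.times_to_peak)):
            levels = tuple(float(x) for x in levels)
            object.__setattr__(self, name, levels)
            if any(x <= 0 for x in levels):
                raise ValueError(f"{name} must all be positive")
            if len(set(levels)) != len(levels):
                raise ValueError(f"{name} contains duplicates")

    @property
    def size(self) -> int:
        return len(self.peak_velocities) * len(self.times_to_peak)


@dataclass(frozen=True)
class PendulumSpec:
    """Pendulum impact: impactor velocity (m/s) and mass (kg), ballast (kg)."""

    impact_velocity: float
    pendulum_mass: float
    ballast_mass: float

    def __post_init__(self) -> None:
        if self.impact_velocity < 0:
            raise ValueError("impact_velocity must be >= 0")
        if self.pendulum_mass <= 0 or self.ballast_mass <= 0:
            raise ValueError("masses must be positive")

    @property
    def momentum(self) -> float:
        """Impactor momentum in kg m/s."""
        return self.impact_velocity * self.pendulum_mass


def triangular_pulse(spec: PulseSpec, dt: float) -> Signal:
    """Sample the triangular velocity pulse at interval ``dt``.

    ``dt`` must resolve the rise (dt < time_to_peak / 10).
    """
    if dt >= spec.time_to_peak / 10.0:
        raise ValueError(
            f"dt = {dt:g} too coarse for time_to_peak {spec.time_to_peak:g}"
        )
    n = int(np.round(spec.total_duration / dt)) + 1
    t = dt * np.arange(n)
    v = np.zeros(n)
    rise = t <= spec.time_to_peak
    v[rise] = spec.peak_velocity * t[rise] / spec.time_to_peak
    if spec.fall_time > 0:
        t_end = spec.time_to_peak + spec.fall_time
        fall = (t > spec.time_to_peak) & (t < t_end)
        v[fall] = spec.peak_velocity * (t_end - t[fall]) / spec.fall_time
    return Signal(0.0, dt, v, unit="m/s")


def build_grid(grid: LoadingGrid) -> list[PulseSpec]:
    """Full-factorial pulse list, velocity-major order.

    Consecutive blocks share a peak velocity and step through the times to
    peak, matching the conventional numbering of UBB sweep combinations.
    """
    if not grid.peak_velocities or not grid.times_to_peak:
        raise ValueError("grid level lists must be non-empty")
    return [PulseSpec(v, ttp)
            for v in grid.peak_velocities
            for ttp in grid.times_to_peak]


def pendulum_conditions(spec: PendulumSpec) -> dict:
    """Initial-state record for the simulator in pendulum (impactor) mode."""
    return {
        "boundary_mode": "impactor",
        "impactor_mass": spec.pendulum_mass,
        "impactor_velocity": spec.impact_velocity,
        "proximal_mass": spec.ballast_mass,
        "momentum": spec.momentum,
    }


def default_ubb_grid() -> LoadingGrid:
    """The canonical 25-point UBB sweep: 5 peak velocities x 5 times to peak.

    Peak velocities 5-30 m/s, times to peak 1.5-9 ms.
    """
    return LoadingGrid(
        peak_velocities=(5.0, 11.25, 17.5, 23.75, 30.0),
        times_to_peak=(1.5e-3, 3.5e-3, 5e-3, 7e-3, 9e-3),
    )


def load_grid(path: str | Path) -> LoadingGrid:
    """Read grid levels from a YAML-syntax ``.cfg`` file."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    return LoadingGrid(tuple(raw["peak_velocities"]),
                       tuple(raw["times_to_peak"]))


def load_pendulum_modalities(path: str | Path) -> list[PendulumSpec]:
    """Read a list of pendulum test modalities from a ``.cfg`` file."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    return [PendulumSpec(m["impact_velocity"], m["pendulum_mass"],
                         m["ballast_mass"]) for m in raw["modalities"]]
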