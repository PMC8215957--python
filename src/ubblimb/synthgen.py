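"""Synthetic test fixtures.

No experimental rig records are publicly deposited, so fixtures are
generated: the simulator is run at known ("true") parameters and its outputs
are sampled at the experimental rate (25 kHz) with seeded zero-mean Gaussian
amplitude noise, emulating plate-accelerometer and hindfoot force-sensor
records.  A truth record carries the generating parameters so
parameter-recovery tests can score themselves, and regeneration from the
recorded seed is bit-identical.

Constructed signal pairs with closed-form expected sub-ratings (pure
scaling, pure delay, constant offset of a half-sine) provide golden inputs
for the rating module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import AnubisScenario
from .loading import triangular_pulse
from .rating import RatingSettings, evaluation_window
from .signals import Signal, resample

__all__ = ["FixtureSpec", "make_reference", "make_rating_pair"]

EXPERIMENTAL_FS = 25e3  # Hz


@dataclass
class FixtureSpec:
    """Recipe for a synthetic rig record.

    ``true_k`` / ``true_scale`` are the generating grid-point parameters;
    ``noise_fraction`` scales the Gaussian noise standard deviation relative
    to the peak absolute signal value.
    """

    scenario: AnubisScenario = field(default_factory=AnubisScenario)
    true_k: float = 240.0
    true_scale: float = 1.0
    noise_fraction: float = 0.0
    seed: int = 0
    fs: float = EXPERIMENTAL_FS

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


def _add_noise(sig: Signal, fraction: float,
               rng: np.random.Generator) -> Signal:
    if fraction == 0.0:
        return sig
    sd = fraction * np.abs(sig.values).max()
    return sig.with_values(sig.values + rng.normal(0.0, sd, sig.n))


def make_reference(spec: FixtureSpec) -> tuple[Signal, Signal, dict]:
    """Synthesize (hindfoot force, plate acceleration, truth record).

    The hindfoot force is the simulated plate-contact force at the true
    parameters resampled to ``spec.fs``; the plate acceleration is the
    derivative of the prescribed triangular velocity pulse.  Both carry
    independent noise streams drawn from one seeded generator.
    """
    rng = np.random.default_rng(spec.seed)
    sim = spec.scenario.simulate(spec.true_k, spec.true_scale)
    force = resample(sim, 1.0 / spec.fs)
    force = _add_noise(force, spec.noise_fraction, rng)

    vel = triangular_pulse(spec.scenario.pulse, 1.0 / spec.fs)
    accel = Signal(vel.t0, vel.dt, np.gradient(vel.values, vel.dt),
                   unit="m/s^2")
    accel = _add_noise(accel, spec.noise_fraction, rng)

    truth = {
        "true_k": spec.true_k,
        "true_scale": spec.true_scale,
        "noise_fraction": spec.noise_fraction,
        "seed": spec.seed,
        "fs": spec.fs,
        "pulse_peak_velocity": spec.scenario.pulse.peak_velocity,
        "pulse_time_to_peak": spec.scenario.pulse.time_to_peak,
    }
    return force, accel, truth


def make_rating_pair(kind: str, magnitude_factor: float = 1.1,
                     shift: float = 0.0, offset: float = 0.5,
                     settings: RatingSettings = RatingSettings()
                     ) -> tuple[Signal, Signal, dict]:
    """Construct (reference, comparison, expected sub-ratings).

    The reference is a unit half-sine pulse (10 ms, 25 kHz).  ``kind``:

    * ``"scaled"`` — comparison is ``magnitude_factor * reference``;
      expected magnitude rating ``1 - |factor - 1|``;
    * ``"shifted"`` — comparison is the reference delayed by ``shift``
      seconds (rounded to a whole sample); expected phase rating
      ``1 - |shift| / delta_max``;
    * ``"offset"`` — comparison is ``reference + offset``; expected slope
      rating 1 (derivatives are offset-invariant).
    """
    dt = 1.0 / EXPERIMENTAL_FS
    n = 512
    t = dt * np.arange(n)
    t_pulse = 10e-3
    ref_vals = np.where(t <= t_pulse, np.sin(np.pi * t / t_pulse), 0.0)
    ref = Signal(0.0, dt, ref_vals, unit="N")

    i0, i1 = evaluation_window(ref, settings)
    delta_max = settings.delta_max_fraction * (i1 - i0) * dt

    if kind == "scaled":
        cmp_ = ref.with_values(magnitude_factor * ref_vals)
        expected = {"magnitude": max(0.0, 1.0 - abs(magnitude_factor - 1.0))}
    elif kind == "shifted":
        s = int(round(shift / dt))
        vals = np.zeros(n)
        if s >= 0:
            vals[s:] = ref_vals[:n - s]
        else:
            vals[:n + s] = ref_vals[-s:]
        cmp_ = ref.with_values(vals)
        expected = {"phase": max(0.0, 1.0 - abs(s * dt) / delta_max)}
    elif kind == "offset":
        cmp_ = ref.with_values(ref_vals + offset)
        expected = {"slope": 1.0}
    else:
        raise ValueError(f"unknown rating-pair kind {kind!r}")
    expected["delta_max"] = delta_max
    return ref, cmp_, expected
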