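"""Uniformly sampled time-series signals and impact-test signal conditioning.

The :class:`Signal` container is the common currency of the package: measured
or simulated force, acceleration, velocity and displacement histories are all
uniformly sampled series with a start time, a sample interval and a unit tag.
Conditioning follows impact-test practice: channel-frequency-class (CFC)
filtering applies the SAE J211 phaseless two-pole Butterworth forward and
backward, and plate accelerometer records are integrated to velocity with the
cumulative trapezoidal rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as _sps
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "Signal",
    "FilterSpec",
    "apply_filter",
    "integrate_to_velocity",
    "peak",
    "resample",
    "read_csv",
    "write_csv",
    "read_hdf5",
    "write_hdf5",
]


@dataclass
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    t0 : float
        Time of the first sample in seconds.
    dt : float
        Sample interval in seconds; must be positive.
    values : numpy.ndarray
        Sample values; at least two finite samples.
    unit : str
        Unit label, e.g. ``"N"``, ``"m/s^2"``, ``"m/s"``, ``"m"``.
    """

    t0: float
    dt: float
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("signal needs at least 2 samples in a 1-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        return self.dt * (self.n - 1)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Signal":
        return replace(self, values=np.asarray(values, dtype=float),
                       unit=self.unit if unit is None else unit)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter specification.

    ``kind`` is ``"CFC"`` (channel frequency class, SAE J211 phaseless
    convention) or ``"butterworth_lowpass"``.  ``cutoff`` carries the channel
    class for CFC (e.g. 1000) and the -3 dB cutoff in Hz for Butterworth.
    """

    kind: str
    cutoff: float
    order: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("CFC", "butterworth_lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff/channel class must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "FilterSpec":
        """Parse a compact spec like ``cfc:1000`` or ``butter:1000:2``."""
        parts = text.split(":")
        kind = parts[0].lower()
        if kind == "cfc":
            return cls("CFC", float(parts[1]))
        if kind in ("butter", "butterworth", "butterworth_lowpass"):
            order = int(parts[2]) if len(parts) > 2 else 2
            return cls("butterworth_lowpass", float(parts[1]), order)
        raise ValueError(f"cannot parse filter spec {text!r}")


def _j211_coefficients(cfc: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-pole Butterworth coefficients per the SAE J211 formula.

    One forward plus one backward pass of this 2-pole section yields the
    standard 4-pole phaseless CFC response.
    """
    wd = 2.0 * np.pi * cfc * 2.0775
    wa = np.tan(wd * dt / 2.0)
    denom = 1.0 + np.sqrt(2.0) * wa + wa * wa
    a0 = wa * wa / denom
    a1 = 2.0 * a0
    a2 = a0
    b1 = -2.0 * (wa * wa - 1.0) / denom
    b2 = (-1.0 + np.sqrt(2.0) * wa - wa * wa) / denom
    # scipy convention: a[0]*y[n] = b@x - a[1:]@y
    return np.array([a0, a1, a2]), np.array([1.0, -b1, -b2])


def _effective_cutoff_hz(spec: FilterSpec) -> float:
    # CFC class N has its -3 dB point near 1.65*N Hz; use the J211 design
    # frequency for the Nyquist guard.
    if spec.kind == "CFC":
        return spec.cutoff * 2.0775
    return spec.cutoff


def apply_filter(sig: Signal, spec: FilterSpec) -> Signal:
    """Filter a signal with zero phase distortion (forward-backward pass).

    CFC filtering uses the SAE J211 digital two-pole coefficients applied
    forward and backward (the standard phaseless 4-pole response).  The
    Butterworth branch designs an ``order``-pole low-pass and likewise applies
    it forward-backward.  Edges are handled by reflective padding of three
    filter lengths to suppress start-up transients on short impact records.

    Raises
    ------
    ValueError
        If the cutoff reaches the Nyquist frequency or the record is shorter
        than about three filter lengths.
    """
    nyquist = 0.5 * sig.fs
    f_design = _effective_cutoff_hz(spec)
    if f_design >= nyquist:
        raise ValueError(
            f"cutoff {f_design:g} Hz at/above Nyquist {nyquist:g} Hz"
        )
    if spec.kind == "CFC":
        b, a = _j211_coefficients(spec.cutoff, sig.dt)
    else:
        b, a = _sps.butter(spec.order, spec.cutoff, fs=sig.fs)
    ntaps = max(len(a), len(b))
    padlen = 3 * ntaps
    if sig.n <= padlen:
        raise ValueError(
            f"signal too short ({sig.n} samples) for filter padding {padlen}"
        )
    out = _sps.filtfilt(b, a, sig.values, padtype="even", padlen=padlen)
    return sig.with_values(out)


def integrate_to_velocity(accel: Signal, v0: float = 0.0) -> Signal:
    """Integrate an acceleration record to velocity (trapezoidal rule).

    ``accel`` must be tagged with an acceleration unit (``m/s^2``); the result
    is tagged ``m/s`` and shares the time base.
    """
    if _canonical_unit(accel.unit) != "m/s^2":
        raise ValueError(
            f"expected an acceleration signal (m/s^2), got unit {accel.unit!r}"
        )
    vel = v0 + cumulative_trapezoid(accel.values, dx=accel.dt, initial=0.0)
    return Signal(accel.t0, accel.dt, vel, unit="m/s")


def _canonical_unit(unit: str) -> str:
    u = unit.strip().replace(" ", "")
    aliases = {"m/s2": "m/s^2", "m/s²": "m/s^2", "ms^-2": "m/s^2", "g": "g"}
    return aliases.get(u, u)


def peak(sig: Signal) -> tuple[float, float]:
    """Return ``(time, value)`` of the maximum sample (earliest on ties)."""
    i = int(np.argmax(sig.values))
    return sig.t0 + i * sig.dt, float(sig.values[i])


def resample(sig: Signal, dt_new: float) -> Signal:
    """Linearly resample onto a new uniform grid over the same support."""
    if dt_new <= 0:
        raise ValueError("dt_new must be positive")
    t_end = sig.t0 + sig.duration
    n_new = int(np.floor((t_end - sig.t0) / dt_new + 1e-9)) + 1
    if n_new < 2:
        raise ValueError("dt_new too coarse: fewer than 2 samples would remain")
    t_new = sig.t0 + dt_new * np.arange(n_new)
    vals = np.interp(t_new, sig.times, sig.values)
    return Signal(sig.t0, dt_new, vals, unit=sig.unit)


# ---------------------------------------------------------------------------
# File I/O: two-column delimited text (time, value) with a one-line header
# naming the unit, matching typical lab-export conventions.
# ---------------------------------------------------------------------------

def write_csv(sig: Signal, path: str | Path) -> None:
    path = Path(path)
    unit = sig.unit or "-"
    with path.open("w") as fh:
        fh.write(f"time[s],value[{unit}]\n")
        for t, v in zip(sig.times, sig.values):
            fh.write(f"{t:.9g},{v:.9g}\n")


def read_csv(path: str | Path) -> Signal:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        data = np.loadtxt(fh, delimiter=",")
    unit = ""
    if "[" in header:
        unit = header.rsplit("[", 1)[1].rstrip("]").strip()
        if unit == "-":
            unit = ""
    t = data[:, 0]
    dts = np.diff(t)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return Signal(float(t[0]), dt, data[:, 1], unit=unit)


def write_hdf5(path: str | Path, channels: dict[str, Signal]) -> None:
    """Write one dataset per channel with (t0, dt, unit) attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name, sig in channels.items():
            ds = fh.create_dataset(name, data=sig.values)
            ds.attrs["t0"] = sig.t0
            ds.attrs["dt"] = sig.dt
            ds.attrs["unit"] = sig.unit


def read_hdf5(path: str | Path) -> dict[str, Signal]:
    import h5py

    out: dict[str, Signal] = {}
    with h5py.File(path, "r") as fh:
        for name, ds in fh.items():
            out[name] = Signal(
                float(ds.attrs["t0"]), float(ds.attrs["dt"]),
                np.asarray(ds[...]), unit=str(ds.attrs.get("unit", "")),
            )
    return out
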