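"""Objective time-history comparison ratings (ISO 18571 / CORA style).

Two signals — a reference (experiment) and a comparison (simulation) — are
scored on a common time base by four sub-ratings in [0, 1]:

* **phase**: cross-correlation lag within an admissible window ``delta_max``,
  scored 1 at zero lag, 0 at ``delta_max``;
* **magnitude**: one minus the normalized area discrepancy
  ``int |c - r| / int |r|`` after phase alignment;
* **slope**: the same discrepancy applied to first time-derivatives;
* **corridor**: per-sample score against inner/outer corridors built from
  the reference peak, time-averaged.

The overall ISO-style score weights (corridor 0.4, phase 0.2, magnitude 0.2,
slope 0.2).  A secondary "paper mode" reports the unweighted mean of
(magnitude, phase, slope) — the averaging used when a single figure of merit
is quoted for a calibrated model.  Scores map to qualitative grades:
Excellent (>= 0.94), Good (>= 0.80), Fair (>= 0.58), Poor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import Signal, resample

__all__ = [
    "RatingReport",
    "RatingSettings",
    "phase_rating",
    "magnitude_rating",
    "slope_rating",
    "corridor_rating",
    "rate",
    "grade",
    "evaluation_window",
    "paper_mode_average",
    "GRADE_BANDS",
]

GRADE_BANDS = (("Excellent", 0.94), ("Good", 0.80), ("Fair", 0.58),
               ("Poor", 0.0))

ISO_WEIGHTS = {"corridor": 0.4, "phase": 0.2, "magnitude": 0.2, "slope": 0.2}


@dataclass(frozen=True)
class RatingSettings:
    """Module defaults for the rating parameters.

    The exact parameter values used by the reference CORA tooling are not
    standardized in print; these are this module's defaults.  ``delta_max``
    is expressed as a fraction of the evaluation-window length;
    ``inner``/``outer`` are corridor half-widths as fractions of the
    reference peak; ``window_threshold`` sets the auto-window onset/decay
    level as a fraction of the reference peak.
    """

    delta_max_fraction: float = 0.20
    inner: float = 0.05
    outer: float = 0.50
    window_threshold: float = 0.05


@dataclass
class RatingReport:
    magnitude: float
    phase: float
    slope: float
    corridor: float
    overall: float
    grade: str
    window: tuple[float, float]
    phase_shift: float = 0.0
    paper_average: float | None = None


def grade(score: float) -> str:
    """Map a score in [0, 1] to its qualitative grade band."""
    if not 0.0 <= score <= 1.0 + 1e-12:
        raise ValueError(f"score {score} outside [0, 1]")
    for label, lo in GRADE_BANDS:
        if score >= lo:
            return label
    return "Poor"  # pragma: no cover


def evaluation_window(reference: Signal,
                      settings: RatingSettings = RatingSettings()
                      ) -> tuple[int, int]:
    """Auto window: first to last sample above ``threshold * peak |r|``.

    Returns half-open sample indices ``(i0, i1)``.
    """
    r = np.abs(reference.values)
    peak = r.max()
    if peak <= 0:
        raise ValueError("degenerate (all-zero) reference signal")
    above = np.nonzero(r >= settings.window_threshold * peak)[0]
    return int(above[0]), int(above[-1]) + 1


def _common_base(reference: Signal, comparison: Signal
                 ) -> tuple[Signal, Signal]:
    if abs(reference.dt - comparison.dt) > 1e-12 * reference.dt:
        comparison = resample(comparison, reference.dt)
    n = min(reference.n, comparison.n)
    return (reference.with_values(reference.values[:n]),
            comparison.with_values(comparison.values[:n]))


def phase_rating(reference: Signal, comparison: Signal,
                 settings: RatingSettings = RatingSettings()
                 ) -> tuple[float, float]:
    """Phase score and the recovered shift (s) of comparison vs reference.

    The shift is the argmax of the normalized cross-correlation over lags
    within ``+-delta_max``; the score decays linearly from 1 at zero lag to
    0 at ``delta_max``.  A constant reference is degenerate and rejected.
    """
    ref, cmp_ = _common_base(reference, comparison)
    if np.ptp(ref.values) == 0:
        raise ValueError("degenerate (constant) reference: phase undefined")
    i0, i1 = evaluation_window(ref, settings)
    delta_max = settings.delta_max_fraction * (i1 - i0) * ref.dt
    smax = max(1, int(round(delta_max / ref.dt)))
    r = ref.values[i0:i1]
    c = cmp_.values
    n = i1 - i0
    best_s, best_corr = 0, -np.inf
    r_norm = np.sqrt(np.dot(r, r))
    for s in range(-smax, smax + 1):
        lo = i0 + s
        seg = np.zeros(n)
        a, b = max(lo, 0), min(lo + n, c.size)
        if b > a:
            seg[a - lo:b - lo] = c[a:b]
        c_norm = np.sqrt(np.dot(seg, seg))
        if c_norm == 0 or r_norm == 0:
            corr = -np.inf
        else:
            corr = np.dot(r, seg) / (r_norm * c_norm)
        if corr > best_corr:
            best_corr, best_s = corr, s
    shift = best_s * ref.dt
    score = max(0.0, 1.0 - abs(shift) / delta_max)
    return score, shift


def _aligned_window(reference: Signal, comparison: Signal,
                    settings: RatingSettings,
                    shift: float | None) -> tuple[np.ndarray, np.ndarray,
                                                  float, tuple[int, int]]:
    ref, cmp_ = _common_base(reference, comparison)
    i0, i1 = evaluation_window(ref, settings)
    if shift is None:
        _, shift = phase_rating(reference, comparison, settings)
    s = int(round(shift / ref.dt))
    n = i1 - i0
    seg = np.zeros(n)
    lo = i0 + s
    a, b = max(lo, 0), min(lo + n, cmp_.n)
    if b > a:
        seg[a - lo:b - lo] = cmp_.values[a:b]
    return ref.values[i0:i1], seg, ref.dt, (i0, i1)


def magnitude_rating(reference: Signal, comparison: Signal,
                     settings: RatingSettings = RatingSettings(),
                     shift: float | None = None) -> float:
    """``1 - int |c - r| / int |r|`` over the window, clipped to [0, 1]."""
    r, c, dt, _ = _aligned_window(reference, comparison, settings, shift)
    norm = np.trapezoid(np.abs(r), dx=dt)
    if norm <= 0:
        raise ValueError("zero-norm reference over the evaluation window")
    disc = np.trapezoid(np.abs(c - r), dx=dt) / norm
    return float(np.clip(1.0 - disc, 0.0, 1.0))


def slope_rating(reference: Signal, comparison: Signal,
                 settings: RatingSettings = RatingSettings(),
                 shift: float | None = None) -> float:
    """Magnitude-style discrepancy on central-difference derivatives."""
    r, c, dt, _ = _aligned_window(reference, comparison, settings, shift)
    dr = np.gradient(r, dt)
    dc = np.gradient(c, dt)
    norm = np.trapezoid(np.abs(dr), dx=dt)
    if norm <= 0:
        raise ValueError("zero-slope reference over the evaluation window")
    disc = np.trapezoid(np.abs(dc - dr), dx=dt) / norm
    return float(np.clip(1.0 - disc, 0.0, 1.0))


def corridor_rating(reference: Signal, comparison: Signal,
                    inner: float | None = None, outer: float | None = None,
                    settings: RatingSettings = RatingSettings(),
                    shift: float | None = None) -> float:
    """Time-averaged corridor score.

    Inner corridor ``reference +- inner * peak`` scores 1, outer corridor
    ``+- outer * peak`` scores 0, linear in between.
    """
    inner = settings.inner if inner is None else inner
    outer = settings.outer if outer is None else outer
    if outer <= inner:
        raise ValueError("outer corridor must exceed inner corridor")
    r, c, dt, _ = _aligned_window(reference, comparison, settings, shift)
    peak = np.abs(r).max()
    if peak <= 0:
        raise ValueError("zero-peak reference over the evaluation window")
    dev = np.abs(c - r)
    lo, hi = inner * peak, outer * peak
    score = np.clip((hi - dev) / (hi - lo), 0.0, 1.0)
    return float(score.mean())


def rate(reference: Signal, comparison: Signal,
         weights: dict[str, float] | None = None,
         settings: RatingSettings = RatingSettings(),
         mode: str = "iso") -> RatingReport:
    """Full rating report.

    ``mode="iso"`` weights (corridor, phase, magnitude, slope) by the default
    weights; ``mode="paper"`` sets the overall score to the unweighted mean
    of (magnitude, phase, slope).  Both modes populate ``paper_average``.
    """
    if mode not in ("iso", "paper"):
        raise ValueError(f"unknown rating mode {mode!r}")
    w = dict(ISO_WEIGHTS)
    if weights:
        w.update(weights)
    ph, shift = phase_rating(reference, comparison, settings)
    mag = magnitude_rating(reference, comparison, settings, shift)
    slo = slope_rating(reference, comparison, settings, shift)
    cor = corridor_rating(reference, comparison, settings=settings,
                          shift=shift)
    paper_avg = (mag + ph + slo) / 3.0
    if mode == "paper":
        overall = paper_avg
    else:
        overall = (w["corridor"] * cor + w["phase"] * ph
                   + w["magnitude"] * mag + w["slope"] * slo)
    ref, _ = _common_base(reference, comparison)
    i0, i1 = evaluation_window(ref, settings)
    window = (ref.t0 + i0 * ref.dt, ref.t0 + (i1 - 1) * ref.dt)
    return RatingReport(magnitude=mag, phase=ph, slope=slo, corridor=cor,
                        overall=overall, grade=grade(overall), window=window,
                        phase_shift=shift, paper_average=paper_avg)


def paper_mode_average(sub_ratings) -> float:
    """Unweighted mean of (magnitude, phase, slope) sub-ratings."""
    vals = list(sub_ratings)
    if len(vals) != 3:
        raise ValueError("expected exactly (magnitude, phase, slope)")
    return float(np.mean(vals))
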