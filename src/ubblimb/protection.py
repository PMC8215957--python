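"""Injury-risk curves and combat-boot protection assessment.

Peak axial proximal-tibia force maps to a probability of calcaneal fracture
through severity-specific risk curves: *minor* corresponds to a Sanders-I
fracture (< 2 mm articular displacement), *major* to Sanders-II (at least
one primary fracture line).  The protection sweep runs the loading grid in
booted and unbooted configurations, tabulates peak proximal forces, signed
percent force differences and the change in injury probability per severity,
and summarizes the two force populations with normal fits and a two-sample
t-test.

The risk-curve parameters derive from a companion survival analysis whose
curves are not reproduced here; the shipped ``riskcurves.cfg`` holds
placeholder logistic curves constructed to match two published worked
examples, and their placeholder status is logged at load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .limb_model import ChainModel, SimulationError, run
from .loading import LoadingGrid, build_grid
from .signals import peak

__all__ = [
    "RiskCurve",
    "ProtectionReport",
    "risk_probability",
    "load_risk_curves",
    "sweep",
    "summarize",
    "table_aggregates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RiskCurve:
    """Force-to-probability mapping for one injury severity.

    ``form`` is ``"logistic"`` (``p = 1/(1+exp(-(F-location)/scale))``) or
    ``"lognormal"`` (``p = Phi((ln F - ln location)/scale)``); ``location``
    is in N.
    """

    severity: str
    form: str
    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.form not in ("logistic", "lognormal"):
            raise ValueError(f"unknown risk-curve form {self.form!r}")
        if self.location <= 0 or self.scale <= 0:
            raise ValueError("location and scale must be positive")

    def probability(self, force: float) -> float:
        if self.form == "logistic":
            return float(1.0 / (1.0 + np.exp(-(force - self.location)
                                             / self.scale)))
        if force <= 0:
            return 0.0
        z = (np.log(force) - np.log(self.location)) / self.scale
        return float(stats.norm.cdf(z))


def risk_probability(force: float, curve: RiskCurve) -> float:
    """Probability of injury at the given peak proximal tibia force (N)."""
    if force < 0:
        raise ValueError("force must be non-negative")
    return curve.probability(force)


def load_risk_curves(path: str | Path) -> dict[str, RiskCurve]:
    """Load severity-keyed risk curves from a YAML-syntax ``.cfg`` file."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    curves: dict[str, RiskCurve] = {}
    for severity, entry in raw.items():
        entry = dict(entry)
        placeholder = entry.pop("placeholder", False)
        curves[severity] = RiskCurve(severity=severity, **entry)
        if placeholder:
            logger.warning(
                "risk curve %r loaded from %s is a placeholder calibrated "
                "to published worked examples, not the original survival "
                "analysis", severity, path)
    return curves


@dataclass
class ProtectionReport:
    """Booted-vs-unbooted comparison over a loading grid.

    ``table`` columns: time_to_peak_ms, peak_velocity_m_s, unbooted_force_N,
    booted_force_N, pct_difference (signed, negative = boot reduces force),
    delta_p_minor, delta_p_major (percentage points), valid flag.
    """

    table: pd.DataFrame

    def valid(self) -> pd.DataFrame:
        return self.table[self.table["valid"]]


def sweep(grid: LoadingGrid, unbooted: ChainModel, booted: ChainModel,
          curves: dict[str, RiskCurve] | None = None, *,
          dt: float = 1e-7, output_dt: float = 1e-5) -> ProtectionReport:
    """Run both configurations for every pulse in the grid.

    The two chains must differ only in boot presence.  Percent difference is
    ``100 (booted - unbooted)/unbooted`` on peak proximal force; probability
    changes are ``100 (p_booted - p_unbooted)`` per severity.  A pulse whose
    simulation aborts is flagged invalid and excluded from summaries.
    """
    if unbooted.boot_present or not booted.boot_present:
        raise ValueError("expected (unbooted, booted) chain pair")
    rows = []
    for spec in build_grid(grid):
        row = {
            "time_to_peak_ms": spec.time_to_peak * 1e3,
            "peak_velocity_m_s": spec.peak_velocity,
            "unbooted_force_N": np.nan, "booted_force_N": np.nan,
            "pct_difference": np.nan,
            "delta_p_minor": np.nan, "delta_p_major": np.nan,
            "valid": False, "diagnostic": "",
        }
        try:
            res_u = run(unbooted, spec, dt=dt, output_dt=output_dt)
            res_b = run(booted, spec, dt=dt, output_dt=output_dt)
        except SimulationError as err:
            row["diagnostic"] = str(err)
            logger.warning("pulse (%.3g m/s, %.3g ms) failed: %s",
                           spec.peak_velocity, spec.time_to_peak * 1e3, err)
            rows.append(row)
            continue
        _, f_u = peak(res_u.proximal_force)
        _, f_b = peak(res_b.proximal_force)
        row.update(unbooted_force_N=f_u, booted_force_N=f_b,
                   pct_difference=100.0 * (f_b - f_u) / f_u, valid=True)
        if curves:
            for severity in ("minor", "major"):
                if severity in curves:
                    dp = (risk_probability(f_b, curves[severity])
                          - risk_probability(f_u, curves[severity]))
                    row[f"delta_p_{severity}"] = 100.0 * dp
        rows.append(row)
    return ProtectionReport(table=pd.DataFrame(rows))


def summarize(report: ProtectionReport) -> dict:
    """Normal fits per configuration and a pooled two-sample t-test.

    Returns sample means and standard deviations of the peak proximal force
    populations, the t statistic, p-value and the 5%-level rejection
    decision for equal means.
    """
    df = report.valid()
    if len(df) < 3:
        raise ValueError("need at least 3 valid rows per configuration")
    x = df["unbooted_force_N"].to_numpy()
    y = df["booted_force_N"].to_numpy()
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
        t_stat, p_val = 0.0, 1.0  # degenerate: identical constant samples
    else:
        t_stat, p_val = stats.ttest_ind(x, y, equal_var=True)
    return {
        "n": len(df),
        "unbooted_mean": float(x.mean()),
        "unbooted_sd": float(x.std(ddof=1)),
        "booted_mean": float(y.mean()),
        "booted_sd": float(y.std(ddof=1)),
        "t_statistic": float(t_stat),
        "p_value": float(p_val),
        "reject_equal_means_5pct": bool(p_val < 0.05),
    }


def table_aggregates(table: pd.DataFrame,
                     columns: tuple[str, ...] = ("delta_p_minor",
                                                 "delta_p_major")
                     ) -> dict[str, tuple[float, float]]:
    """(min, max) absolute reduction per severity column of a report table."""
    if len(table) == 0:
        raise ValueError("empty table")
    out = {}
    for col in columns:
        vals = np.abs(table[col].dropna().to_numpy())
        out[col] = (float(vals.min()), float(vals.max()))
    return out
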