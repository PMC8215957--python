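"""One-dimensional constitutive laws for the reduced-order limb chain.

Unit conventions (bone-literature standard, used throughout the material
library files): density in g/cm^3, elastic moduli in GPa, yield stress in
MPa, quasi-linear-viscoelastic (QLV) scale ``A`` in MPa, spring stiffness in
N/mm.  Operations return MPa for stresses and N for forces.

Laws provided:

* linear elasticity (trabecular bone, cartilage, mild steel);
* piecewise linear plasticity with a rate-switched modulus and bilinear
  hardening (cortical bone);
* quasi-linear viscoelasticity: exponential instantaneous backbone
  ``sigma_e = A (exp(B eps) - 1)`` convolved with a one-term reduced
  relaxation function ``G(t) = (1 + Q exp(-t/tau)) / (1 + Q)`` (heel fat pad,
  plantar tissue);
* incompressible two-constant Mooney-Rivlin uniaxial response (plantar
  tissue backbone used for calibration scaling);
* tension-only piecewise-linear springs (ligaments, plantar fascia).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .signals import Signal

__all__ = [
    "ElasticParams",
    "PlasticParams",
    "QLVParams",
    "HyperelasticParams",
    "SpringCurve",
    "elastic_stress",
    "plastic_stress",
    "qlv_force",
    "qlv_relaxation",
    "mooney_rivlin_uniaxial",
    "spring_force",
    "MaterialLibrary",
    "load_library",
]


@dataclass(frozen=True)
class ElasticParams:
    """Linear elasticity: density (g/cm^3), modulus E (GPa), Poisson nu."""

    rho: float
    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.E <= 0:
            raise ValueError("rho and E must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")


@dataclass(frozen=True)
class PlasticParams:
    """Piecewise linear plasticity with strain-rate modulus switching.

    The elastic modulus is ``E_quasistatic`` below ``rate_threshold`` (1/s)
    and ``E_dynamic`` at or above it.  ``tangent_modulus`` is the post-yield
    slope (GPa); 0 gives perfect plasticity.
    """

    rho: float
    E_quasistatic: float
    E_dynamic: float
    nu: float
    yield_stress: float  # MPa
    tangent_modulus: float = 0.0  # GPa
    rate_threshold: float = 1.0  # 1/s

    def __post_init__(self) -> None:
        if self.yield_stress <= 0:
            raise ValueError("yield stress must be positive")
        if not 0.0 <= self.tangent_modulus < min(self.E_quasistatic,
                                                 self.E_dynamic):
            raise ValueError("tangent modulus must be in [0, E)")

    def modulus(self, strain_rate: float) -> float:
        """Elastic modulus (GPa) for the given strain rate."""
        return (self.E_dynamic if strain_rate >= self.rate_threshold
                else self.E_quasistatic)


@dataclass(frozen=True)
class QLVParams:
    """Quasi-linear viscoelasticity parameters.

    ``A`` (MPa) and ``B`` (dimensionless) set the instantaneous elastic
    backbone ``sigma_e(eps) = A (exp(B eps) - 1)``; ``Q`` is the relaxation
    amplitude and ``tau`` (s) the relaxation time of the one-term reduced
    relaxation function ``G(t) = (1 + Q exp(-t/tau)) / (1 + Q)``.
    """

    A: float
    B: float
    Q: float
    tau: float = 1e-3
    nu: float = 0.495
    rho: float = 0.97

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("A and B must be positive")
        if self.Q < 0:
            raise ValueError("Q must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def backbone(self, strain: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous elastic stress (MPa) at the given strain."""
        return self.A * (np.exp(self.B * np.asarray(strain, dtype=float)) - 1.0)


@dataclass(frozen=True)
class HyperelasticParams:
    """Two-constant incompressible Mooney-Rivlin model (C01, C10 in MPa)."""

    C01: float
    C10: float

    def __post_init__(self) -> None:
        if self.C01 + self.C10 <= 0:
            raise ValueError("C01 + C10 must be positive")


@dataclass(frozen=True)
class SpringCurve:
    """Piecewise-linear force-elongation curve through the origin.

    ``points`` are ``(elongation mm, force N)`` pairs with non-decreasing
    force; extrapolation beyond the last point continues the final slope.
    ``tension_only`` springs carry no load in compression.
    """

    points: tuple[tuple[float, float], ...]
    tension_only: bool = True

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(f)) for x, f in self.points)
        if (0.0, 0.0) not in pts:
            pts = ((0.0, 0.0),) + pts
        pts = tuple(sorted(pts))
        forces = [f for _, f in pts]
        if any(b < a for a, b in zip(forces, forces[1:])):
            raise ValueError("spring force must be non-decreasing")
        object.__setattr__(self, "points", pts)

    @classmethod
    def linear(cls, k: float, tension_only: bool = True,
               x_max: float = 100.0) -> "SpringCurve":
        """A linear curve of stiffness ``k`` N/mm."""
        return cls(((0.0, 0.0), (x_max, k * x_max)), tension_only=tension_only)

    @property
    def k_initial(self) -> float:
        """Slope at the origin in N/mm."""
        xs = [x for x, _ in self.points]
        fs = [f for _, f in self.points]
        i0 = xs.index(0.0)
        if i0 + 1 < len(xs):
            return (fs[i0 + 1] - fs[i0]) / (xs[i0 + 1] - xs[i0])
        return 0.0


def elastic_stress(strain: float, p: ElasticParams) -> float:
    """Linear-elastic stress in MPa (E converted GPa -> MPa)."""
    return p.E * 1e3 * strain


def plastic_stress(strain_history: np.ndarray, p: PlasticParams,
                   strain_rate: float = 0.0) -> np.ndarray:
    """Stress history (MPa) for a 1-d bilinear elastoplastic path.

    Incremental return mapping with isotropic bilinear hardening: loading
    below yield follows the (rate-switched) elastic modulus, beyond yield the
    tangent modulus; unloading is elastic from the furthest plastic state.
    The history must start at zero strain.
    """
    eps = np.asarray(strain_history, dtype=float)
    if eps.size == 0 or eps[0] != 0.0:
        raise ValueError("strain history must start at 0")
    E = p.modulus(strain_rate) * 1e3  # MPa
    Et = p.tangent_modulus * 1e3
    # hardening modulus of the bilinear law: H = E*Et/(E-Et)
    H = E * Et / (E - Et) if Et > 0 else 0.0
    sigma = np.empty_like(eps)
    eps_p = 0.0  # plastic strain
    alpha = 0.0  # accumulated plastic strain (isotropic hardening variable)
    for i, e in enumerate(eps):
        trial = E * (e - eps_p)
        flow = abs(trial) - (p.yield_stress + H * alpha)
        if flow > 0.0:
            dgamma = flow / (E + H)
            eps_p += dgamma * np.sign(trial)
            alpha += dgamma
            trial = E * (e - eps_p)
        sigma[i] = trial
    return sigma


def qlv_relaxation(t: np.ndarray | float, Q: float, tau: float):
    """Reduced relaxation function ``G(t) = (1 + Q exp(-t/tau)) / (1 + Q)``."""
    return (1.0 + Q * np.exp(-np.asarray(t, dtype=float) / tau)) / (1.0 + Q)


def qlv_force(strain: Signal, p: QLVParams, area_scale: float) -> Signal:
    """QLV force response (N) to a uniformly sampled compressive strain.

    The viscoelastic stress is the hereditary convolution of the backbone
    stress rate with the reduced relaxation function,
    ``sigma(t) = int G(t-s) d sigma_e(eps(s))``, evaluated with the exact
    one-term recursive update (unconditionally stable, first-order accurate).
    ``area_scale`` (mm^2) maps MPa to N.
    """
    eps = strain.values
    if np.any(eps < -1e-12):
        raise ValueError("strain must be non-negative (compression magnitude)")
    sig_e = p.backbone(np.clip(eps, 0.0, None))
    g_inf = 1.0 / (1.0 + p.Q)
    g1 = p.Q / (1.0 + p.Q)
    decay = np.exp(-strain.dt / p.tau)
    half = np.exp(-strain.dt / (2.0 * p.tau))
    force = np.empty_like(sig_e)
    h = sig_e[0]  # any initial jump relaxes from t = 0
    force[0] = area_scale * (g_inf * sig_e[0] + g1 * h)
    for i in range(1, sig_e.size):
        h = decay * h + half * (sig_e[i] - sig_e[i - 1])
        force[i] = area_scale * (g_inf * sig_e[i] + g1 * h)
    return Signal(strain.t0, strain.dt, force, unit="N")


def mooney_rivlin_uniaxial(stretch: float, p: HyperelasticParams) -> float:
    """Incompressible uniaxial Cauchy stress (MPa) at the given stretch.

    ``sigma = 2 (lam^2 - 1/lam) (C10 + C01/lam)``.
    """
    lam = float(stretch)
    if lam <= 0:
        raise ValueError("stretch must be positive")
    return 2.0 * (lam * lam - 1.0 / lam) * (p.C10 + p.C01 / lam)


def spring_force(elongation: float, c: SpringCurve) -> float:
    """Piecewise-linear spring force (N) at the given elongation (mm)."""
    x = float(elongation)
    if c.tension_only and x <= 0.0:
        return 0.0
    xs = np.array([p[0] for p in c.points])
    fs = np.array([p[1] for p in c.points])
    if x >= xs[-1]:
        slope = (fs[-1] - fs[-2]) / (xs[-1] - xs[-2]) if len(xs) > 1 else 0.0
        return float(fs[-1] + slope * (x - xs[-1]))
    if x <= xs[0]:
        slope = (fs[1] - fs[0]) / (xs[1] - xs[0]) if len(xs) > 1 else 0.0
        return float(fs[0] + slope * (x - xs[0]))
    return float(np.interp(x, xs, fs))


# ---------------------------------------------------------------------------
# Material library files
# ---------------------------------------------------------------------------

_PARAM_CLASSES = {
    "linear_elastic": ElasticParams,
    "piecewise_linear_plasticity": PlasticParams,
    "qlv": QLVParams,
    "mooney_rivlin": HyperelasticParams,
    "nonlinear_spring": SpringCurve,
}


@dataclass
class MaterialLibrary:
    """Named materials, each a (model kind, parameter object) pair."""

    materials: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, name: str):
        return self.materials[name]

    def __contains__(self, name: str) -> bool:
        return name in self.materials

    def names(self) -> list[str]:
        return sorted(self.materials)


def load_library(path: str | Path) -> MaterialLibrary:
    """Load a keyed material table from a YAML-syntax ``.cfg`` file.

    Each entry maps a material name to ``{model: <kind>, <parameters...>}``.
    Spring materials may give either explicit ``points`` or a stiffness ``k``
    (N/mm).
    """
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    lib = MaterialLibrary()
    for name, entry in raw.items():
        entry = dict(entry)
        kind = entry.pop("model")
        cls = _PARAM_CLASSES[kind]
        if cls is SpringCurve:
            if "k" in entry:
                k = entry.pop("k")
                lib.materials[name] = SpringCurve.linear(
                    k, tension_only=entry.pop("tension_only", True))
            else:
                pts = tuple(tuple(p) for p in entry.pop("points"))
                lib.materials[name] = SpringCurve(
                    pts, tension_only=entry.pop("tension_only", True))
        else:
            lib.materials[name] = cls(**entry)
    return lib
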