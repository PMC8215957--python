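"""Reduced-order lumped-parameter model of the lower limb under plate loading.

The limb is a vertical chain of point masses joined by one-dimensional
elements: loading plate -> (optional combat-boot layers) -> plantar
tissue/heel pad -> foot -> arch + plantar fascia -> ankle/talus ->
tibia+fibula -> proximal mass.  Two boundary modes are supported:

* ``prescribed_plate`` — the plate node follows a prescribed velocity or
  acceleration history (traumatic-injury-simulator rig: plate accelerates to
  a target velocity and arrests, with a 40 kg mass representing the hip
  attachment at the proximal end);
* ``impactor`` — the plate node is a free pendulum mass with an initial
  velocity toward the foot, and the proximal end carries a ballast mass.

Plate contact and soft-tissue blocks are compression-only, so the limb can
separate from the plate.  Time integration is explicit central difference
with a per-step stability re-check; energies (kinetic, internal, external
work) are accumulated every step, so the ledger closes to discretization
error for non-dissipative configurations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .loading import PendulumSpec, PulseSpec, triangular_pulse
from .materials import ElasticParams, QLVParams, SpringCurve
from .signals import Signal, integrate_to_velocity

__all__ = [
    "ChainElement",
    "ChainModel",
    "BootModel",
    "SimulationResult",
    "SimulationError",
    "run",
    "foot_compression",
    "attach_boot",
    "build_limb_chain",
    "default_boot",
    "DEFAULT_GEOMETRY",
    "DEFAULT_SEGMENT_MASSES",
]


class SimulationError(RuntimeError):
    """Raised when a simulation is rejected or aborts (instability)."""


# Geometric scales of the default chain (a 1-d surrogate of the 3-d leg;
# values are nominal adult hindfoot/shank dimensions, all configurable).
DEFAULT_GEOMETRY = {
    "plantar_area_mm2": 1600.0,   # heel + forefoot contact patch
    "plantar_thickness_mm": 20.0,  # heel pad + plantar soft tissue stack
    "arch_stiffness_N_mm": 300.0,  # arch flattening compliance
    "fascia_coupling": 1.0,        # arch-flattening to fascia-stretch ratio
    "ankle_stiffness_N_mm": 5000.0,   # talar cartilage column
    "tibia_stiffness_N_mm": 20000.0,  # tibia+fibula axial stiffness
}

# Segment masses (kg) scaled to a 50th-percentile 72.6 kg adult male:
# foot ~1.45% body mass split between a plantar/forefoot node and an
# ankle/talus node, shank (tibia+fibula+soft tissue) ~4.65% body mass.
DEFAULT_SEGMENT_MASSES = {"foot": 0.75, "ankle": 0.60, "tibia": 3.38}


@dataclass
class ChainElement:
    """One force-carrying element between two chain nodes.

    ``law`` is an integer code from :mod:`ubblimb._kernel`; ``par`` carries
    the law parameters in SI units and ``curve`` optional breakpoints
    ``(deflection m, force N)``.
    """

    name: str
    lo: int
    hi: int
    law: int
    par: tuple[float, ...] = ()
    curve: tuple[tuple[float, float], ...] = ()
    flag: int = _kernel.FLAG_BOTH

    # -- constructors -------------------------------------------------------
    @classmethod
    def linear(cls, name: str, lo: int, hi: int, k_N_mm: float,
               flag: str = "both") -> "ChainElement":
        return cls(name, lo, hi, _kernel.LAW_LINEAR, (k_N_mm * 1e3,),
                   flag=_FLAGS[flag])

    @classmethod
    def from_elastic(cls, name: str, lo: int, hi: int, p: ElasticParams,
                     area_mm2: float, length_mm: float,
                     flag: str = "both") -> "ChainElement":
        k = p.E * 1e3 * area_mm2 / length_mm  # GPa -> MPa; MPa*mm2/mm = N/mm
        return cls.linear(name, lo, hi, k, flag=flag)

    @classmethod
    def qlv(cls, name: str, lo: int, hi: int, p: QLVParams,
            area_mm2: float, thickness_mm: float) -> "ChainElement":
        par = (p.A * 1e6, p.B, thickness_mm * 1e-3, area_mm2 * 1e-6,
               p.Q, p.tau)
        return cls(name, lo, hi, _kernel.LAW_QLV, par,
                   flag=_kernel.FLAG_COMPRESSION)

    @classmethod
    def from_curve(cls, name: str, lo: int, hi: int, c: SpringCurve,
                   flag: str | None = None) -> "ChainElement":
        if flag is None:
            flag = "tension" if c.tension_only else "both"
        pts = tuple((x * 1e-3, f) for x, f in c.points)
        return cls(name, lo, hi, _kernel.LAW_CURVE, (), pts, _FLAGS[flag])

    @classmethod
    def fascia(cls, name: str, lo: int, hi: int, c: SpringCurve,
               coupling: float = 1.0) -> "ChainElement":
        pts = tuple((x * 1e-3, f) for x, f in c.points)
        return cls(name, lo, hi, _kernel.LAW_FASCIA, (coupling,), pts)

    def initial_stiffness(self) -> float:
        """Tangent stiffness (N/m) at zero deflection, for stability checks."""
        if self.law == _kernel.LAW_LINEAR:
            return self.par[0]
        if self.law == _kernel.LAW_QLV:
            A, B, L, area = self.par[0], self.par[1], self.par[2], self.par[3]
            return area / L * A * B
        xs = [p[0] for p in self.curve]
        fs = [p[1] for p in self.curve]
        if len(xs) < 2:
            return 0.0
        k0 = (fs[1] - fs[0]) / (xs[1] - xs[0])
        if self.law == _kernel.LAW_FASCIA:
            return self.par[0] ** 2 * k0
        return k0


_FLAGS = {"both": _kernel.FLAG_BOTH, "compression": _kernel.FLAG_COMPRESSION,
          "tension": _kernel.FLAG_TENSION}


@dataclass
class BootModel:
    """Combat-boot sole stack: ordered compression-only layers.

    Each layer is ``(name, SpringCurve)`` with force-deflection breakpoints
    in (mm, N); ``junction_mass`` (kg) is the lumped mass at each inter-layer
    node.
    """

    layers: list[tuple[str, SpringCurve]]
    junction_mass: float = 0.02

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("boot needs at least one layer")
        for name, curve in self.layers:
            fs = [f for _, f in curve.points]
            if any(f < 0 for f in fs):
                raise ValueError(f"layer {name}: negative force breakpoint")


@dataclass
class ChainModel:
    """The assembled chain: elements, nodal masses and boundary mode."""

    elements: list[ChainElement]
    masses: list[float]
    node_names: list[str]
    boundary_mode: str = "prescribed_plate"
    boot_present: bool = False
    gravity: float = 0.0

    def __post_init__(self) -> None:
        if self.boundary_mode not in ("prescribed_plate", "impactor"):
            raise ValueError(f"unknown boundary mode {self.boundary_mode!r}")
        if len(self.masses) < 2:
            raise ValueError("chain needs at least 2 nodes")
        if any(m <= 0 for m in self.masses):
            raise ValueError("all nodal masses must be positive")
        n = len(self.masses)
        for e in self.elements:
            if not (0 <= e.lo < n and 0 <= e.hi < n and e.lo != e.hi):
                raise ValueError(f"element {e.name}: bad node indices")

    @property
    def n_nodes(self) -> int:
        return len(self.masses)

    def node_index(self, name: str) -> int:
        return self.node_names.index(name)

    def element_index(self, name: str) -> int:
        for i, e in enumerate(self.elements):
            if e.name == name:
                return i
        raise KeyError(name)

    def plate_elements(self) -> list[int]:
        return [i for i, e in enumerate(self.elements) if e.lo == 0]

    def stability_dt(self) -> float:
        """Critical time step 2/omega_max from initial tangent stiffnesses."""
        wmax2 = 0.0
        inv_m = [1.0 / m for m in self.masses]
        if self.boundary_mode == "prescribed_plate":
            inv_m[0] = 0.0
        for e in self.elements:
            k = e.initial_stiffness()
            w2 = k * (inv_m[e.lo] + inv_m[e.hi])
            wmax2 = max(wmax2, w2)
        return 2.0 / np.sqrt(wmax2) if wmax2 > 0 else np.inf


@dataclass
class SimulationResult:
    """Simulation outputs on a common output time base."""

    dt: float
    plate_force: Signal
    proximal_force: Signal
    displacements: np.ndarray  # (n_out, n_nodes), m
    velocities: np.ndarray
    element_forces: np.ndarray  # (n_out, n_elem), N
    energy: pd.DataFrame  # columns: time, kinetic, internal, external, balance
    impulse: float  # time integral of plate contact force, N s
    model: ChainModel = field(repr=False)

    @property
    def times(self) -> np.ndarray:
        return self.plate_force.times

    @property
    def foot_compression(self) -> Signal:
        return foot_compression(self)


def _assemble(model: ChainModel):
    n_elem = len(model.elements)
    max_pts = max((len(e.curve) for e in model.elements), default=0)
    max_pts = max(max_pts, 2)
    e_lo = np.array([e.lo for e in model.elements], dtype=np.int64)
    e_hi = np.array([e.hi for e in model.elements], dtype=np.int64)
    e_law = np.array([e.law for e in model.elements], dtype=np.int64)
    e_flag = np.array([e.flag for e in model.elements], dtype=np.int64)
    par = np.zeros((n_elem, 6))
    c_x = np.zeros((n_elem, max_pts))
    c_f = np.zeros((n_elem, max_pts))
    c_n = np.zeros(n_elem, dtype=np.int64)
    for i, e in enumerate(model.elements):
        for j, v in enumerate(e.par):
            par[i, j] = v
        c_n[i] = len(e.curve)
        for j, (x, f) in enumerate(e.curve):
            c_x[i, j] = x
            c_f[i, j] = f
    masses = np.asarray(model.masses, dtype=float)
    return masses, e_lo, e_hi, e_law, e_flag, par, c_x, c_f, c_n


def _plate_displacement(inp, dt: float, n_steps: int) -> np.ndarray:
    """Prescribed plate displacement at every step boundary (length n+1)."""
    if isinstance(inp, PulseSpec):
        vel = triangular_pulse(inp, dt)
    elif isinstance(inp, Signal):
        if inp.unit in ("m/s^2", "m/s2", "m/s²"):
            vel = integrate_to_velocity(inp)
        elif inp.unit == "m/s":
            vel = inp
        else:
            raise ValueError(
                f"prescribed input must be velocity or acceleration, "
                f"got unit {inp.unit!r}")
        if abs(vel.dt - dt) > 1e-15:
            from .signals import resample
            vel = resample(vel, dt)
    else:
        raise TypeError(f"unsupported input type {type(inp).__name__}")
    v = vel.values
    u = np.zeros(n_steps + 1)
    nv = min(v.size, n_steps + 1)
    u_part = np.concatenate(
        ([0.0], np.cumsum(0.5 * (v[1:nv] + v[:nv - 1]) * dt)))
    u[:nv] = u_part
    u[nv:] = u_part[-1]  # plate at rest after the record ends
    return u


def run(model: ChainModel, inp, dt: float = 1e-7,
        duration: float | None = None, output_dt: float = 1e-5,
        initial_velocities: np.ndarray | None = None) -> SimulationResult:
    """Run the chain under the given input.

    ``inp`` is a :class:`PulseSpec` or velocity/acceleration :class:`Signal`
    in ``prescribed_plate`` mode, or a :class:`PendulumSpec` in ``impactor``
    mode.  ``dt`` must be below the stability limit ``2/omega_max`` of the
    linearized chain (checked at start and re-checked every step).
    """
    dt_crit = model.stability_dt()
    if dt > dt_crit:
        raise SimulationError(
            f"dt = {dt:g} s above the stability limit {dt_crit:g} s")

    if isinstance(inp, PendulumSpec):
        if model.boundary_mode != "impactor":
            raise SimulationError(
                "pendulum input requires an impactor-mode chain")
        if duration is None:
            duration = 0.025
        n_steps = int(np.round(duration / dt))
        plate_u = np.zeros(2)  # unused
        prescribed = False
        v0 = np.zeros(model.n_nodes)
        v0[0] = inp.impact_velocity
        masses, *arrays = _assemble(model)
        masses = masses.copy()
        masses[0] = inp.pendulum_mass
        masses[-1] = inp.ballast_mass
    else:
        if model.boundary_mode != "prescribed_plate":
            raise SimulationError(
                "pulse/signal input requires a prescribed-plate chain")
        if duration is None:
            if isinstance(inp, PulseSpec):
                duration = inp.total_duration + 0.015
            else:
                duration = inp.duration + 0.015
        n_steps = int(np.round(duration / dt))
        plate_u = _plate_displacement(inp, dt, n_steps)
        prescribed = True
        v0 = np.zeros(model.n_nodes)
        masses, *arrays = _assemble(model)

    if initial_velocities is not None:
        v0 = np.asarray(initial_velocities, dtype=float).copy()

    stride = max(1, int(np.round(output_dt / dt)))
    e_lo, e_hi, e_law, e_flag, par, c_x, c_f, c_n = arrays
    (u_hist, v_hist, f_hist, ke, internal, ext,
     impulse, status) = _kernel.run_chain(
        masses, prescribed, plate_u, v0,
        e_lo, e_hi, e_law, e_flag, par, c_x, c_f, c_n,
        dt, n_steps, stride, model.gravity)

    if status != _kernel.STATUS_OK:
        raise SimulationError(
            "simulation aborted: instability detected (tangent stiffness "
            f"exceeded the stability limit at dt = {dt:g} s)")

    dt_out = dt * stride
    plate_f = f_hist[:, model.plate_elements()].sum(axis=1)
    prox_idx = len(model.elements) - 1
    try:
        prox_idx = model.element_index("tibia_proximal")
    except KeyError:
        pass
    if prescribed:
        # total mechanical energy balance: KE + internal - external work
        balance = ke + internal - ext
        ref = np.full_like(ke, max(np.abs(ext).max(), 1e-30))
    else:
        ke0 = 0.5 * masses[0] * v0[0] ** 2 + 0.5 * (
            masses[1:] * np.asarray(v0[1:]) ** 2).sum()
        balance = ke + internal - ke0
        ref = np.full_like(ke, max(ke0, 1e-30))
    energy = pd.DataFrame({
        "time": dt_out * np.arange(len(ke)),
        "kinetic": ke,
        "internal": internal,
        "external": ext if prescribed else np.zeros_like(ext),
        "balance": balance,
        "balance_rel": balance / np.where(ref > 0, ref, np.inf),
    })
    return SimulationResult(
        dt=dt_out,
        plate_force=Signal(0.0, dt_out, plate_f, unit="N"),
        proximal_force=Signal(0.0, dt_out, f_hist[:, prox_idx], unit="N"),
        displacements=u_hist,
        velocities=v_hist,
        element_forces=f_hist,
        energy=energy,
        impulse=float(impulse),
        model=model,
    )


def foot_compression(result: SimulationResult) -> Signal:
    """Compression (mm) of the foot: plate-to-ankle distance reduction.

    The ankle node stands in for the medial malleolus; compression is the
    initial plate-ankle distance minus the current one, i.e.
    ``u_plate - u_ankle`` with upward-positive displacements.
    """
    model = result.model
    try:
        i_ankle = model.node_index("ankle")
    except ValueError as err:
        raise ValueError("model has no 'ankle' node") from err
    comp = (result.displacements[:, 0] - result.displacements[:, i_ankle])
    return Signal(0.0, result.dt, comp * 1e3, unit="mm")


def attach_boot(model: ChainModel, boot: BootModel) -> ChainModel:
    """Insert the boot sole layers between the plate and the plantar tissue.

    Returns a new model (the input is not modified): boot layers become
    compression-only elements in series below the original first element,
    with a lumped junction mass at each new node.
    """
    if model.boot_present:
        raise ValueError("model already has a boot attached")
    n_new = len(boot.layers)
    elements: list[ChainElement] = []
    for i, (name, curve) in enumerate(boot.layers):
        elements.append(ChainElement.from_curve(
            name, i, i + 1, curve, flag="compression"))
    for e in model.elements:
        e2 = copy.deepcopy(e)
        e2.lo = e.lo + n_new if e.lo > 0 else n_new  # plate stays node 0
        e2.hi = e.hi + n_new
        elements.append(e2)
    masses = ([model.masses[0]] + [boot.junction_mass] * n_new
              + list(model.masses[1:]))
    node_names = ([model.node_names[0]]
                  + [f"boot_{name}" for name, _ in boot.layers]
                  + list(model.node_names[1:]))
    return ChainModel(elements, masses, node_names,
                      boundary_mode=model.boundary_mode,
                      boot_present=True, gravity=model.gravity)


def build_limb_chain(plantar: QLVParams, fascia: SpringCurve, *,
                     geometry: dict | None = None,
                     segment_masses: dict | None = None,
                     proximal_mass: float = 40.0,
                     boundary_mode: str = "prescribed_plate",
                     plate_mass: float = 1.0) -> ChainModel:
    """Assemble the default 5-node limb chain.

    Nodes: plate(0) - foot(1) - ankle(2) - tibia(3) - proximal(4).
    Elements: compression-only plantar QLV block; arch spring in parallel
    with the arch-coupled plantar fascia; ankle (cartilage) spring; tibial
    shaft spring whose force is the proximal tibia force.

    ``proximal_mass`` is 40 kg for the rig's hip attachment, or the ballast
    (14/16 kg) in pendulum mode; ``plate_mass`` is only used in impactor
    mode and is normally overridden by the pendulum mass at run time.
    """
    geo = dict(DEFAULT_GEOMETRY)
    if geometry:
        geo.update(geometry)
    seg = dict(DEFAULT_SEGMENT_MASSES)
    if segment_masses:
        seg.update(segment_masses)

    elements = [
        ChainElement.qlv("plantar", 0, 1, plantar,
                         geo["plantar_area_mm2"], geo["plantar_thickness_mm"]),
        ChainElement.linear("arch", 1, 2, geo["arch_stiffness_N_mm"]),
        ChainElement.fascia("plantar_fascia", 1, 2, fascia,
                            coupling=geo["fascia_coupling"]),
        ChainElement.linear("ankle", 2, 3, geo["ankle_stiffness_N_mm"]),
        ChainElement.linear("tibia_proximal", 3, 4,
                            geo["tibia_stiffness_N_mm"]),
    ]
    masses = [plate_mass, seg["foot"], seg["ankle"], seg["tibia"],
              proximal_mass]
    names = ["plate", "foot", "ankle", "tibia", "proximal"]
    return ChainModel(elements, masses, names, boundary_mode=boundary_mode)


def default_boot() -> BootModel:
    """Built-in surrogate combat-boot sole stack.

    The published fitted layer curves of the boot characterization study are
    not reproduced here; these bilinear stiffening curves (initial stiffness,
    densification knee) are surrogate values representative of a rubber
    outsole, polyurethane foam midsole and foam insole, and live in
    ``data/boot.cfg`` for the config route.
    """
    return BootModel(layers=[
        ("outsole", SpringCurve(((0, 0), (2.0, 3000.0), (20.0, 111000.0)),
                                tension_only=False)),
        ("midsole", SpringCurve(((0, 0), (6.0, 2400.0), (30.0, 74400.0)),
                                tension_only=False)),
        ("insole", SpringCurve(((0, 0), (3.0, 900.0), (20.0, 34900.0)),
                               tension_only=False)),
    ], junction_mass=0.02)
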