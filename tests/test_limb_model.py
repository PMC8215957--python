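import math

import numpy as np
import pytest

from ubblimb import config as cfg
from ubblimb.limb_model import (BootModel, ChainElement, ChainModel,
                                SimulationError, attach_boot,
                                build_limb_chain, run)
from ubblimb.loading import PendulumSpec, PulseSpec
from ubblimb.materials import QLVParams, SpringCurve
from ubblimb.signals import Signal, peak

DT = 1e-6  # fast but still ~600x below the stability limit of the chain


def linear_chain(k_N_mm=500.0, masses=(1.0, 2.0),
                 mode="prescribed_plate"):
    n = len(masses)
    elems = [ChainElement.linear(f"s{i}", i, i + 1, k_N_mm)
             for i in range(n - 1)]
    names = ["plate"] + [f"m{i}" for i in range(1, n)]
    return ChainModel(elems, list(masses), names, boundary_mode=mode)


class TestIntegrator:
    def test_zero_input_zero_forces(self, calibrated_chain):
        res = run(calibrated_chain, PulseSpec(0.0, 2e-3), dt=DT,
                  duration=5e-3)
        assert np.allclose(res.plate_force.values, 0.0)
        assert np.allclose(res.proximal_force.values, 0.0)
        assert np.allclose(res.displacements, 0.0)

    def test_harmonic_oscillator_closed_form(self):
        """Mass on a linear spring against a fixed plate follows
        x(t) = (v0/w) sin(wt) within 0.5% over one period at dt = T/1000."""
        k, m, v0 = 1000.0, 2.0, 0.5  # N/m, kg, m/s
        w = math.sqrt(k / m)
        T = 2 * math.pi / w
        dt = T / 1000
        model = linear_chain(k_N_mm=k / 1e3, masses=(1.0, m))
        still = Signal(0.0, dt, np.zeros(1100), unit="m/s")
        res = run(model, still, dt=dt, duration=T, output_dt=dt,
                  initial_velocities=np.array([0.0, v0]))
        t = res.dt * np.arange(res.displacements.shape[0])
        x = res.displacements[:, 1]
        exact = v0 / w * np.sin(w * t)
        assert np.abs(x - exact).max() <= 0.005 * (v0 / w)

    def test_energy_closure_elastic_chain(self):
        """KE + internal - external work closes within 1% of peak external
        work for a purely elastic (Q = 0, no plasticity) chain."""
        plantar = QLVParams(A=0.8, B=2.15, Q=0.0)
        model = build_limb_chain(plantar, SpringCurve.linear(234.6))
        res = run(model, PulseSpec(5.2, 2e-3), dt=DT)
        assert np.abs(res.energy.balance_rel.values).max() < 0.01

    def test_impulse_momentum_closure(self, pendulum_chain):
        """Integral of the plate contact force equals the impactor momentum
        change within 1% (impulse-momentum theorem), using the recorded
        output-rate force history."""
        spec = PendulumSpec(6.7, 23.0, 16.0)
        res = run(pendulum_chain, spec, dt=DT, duration=0.025)
        impulse = np.trapezoid(res.plate_force.values, dx=res.dt)
        dp = spec.pendulum_mass * (spec.impact_velocity
                                   - res.velocities[-1, 0])
        assert impulse == pytest.approx(dp, rel=0.01)

    def test_peak_force_convergence_in_dt(self, calibrated_chain):
        spec = PulseSpec(5.2, 2e-3)
        res1 = run(calibrated_chain, spec, dt=2e-7, duration=0.012)
        res2 = run(calibrated_chain, spec, dt=1e-7, duration=0.012)
        for attr in ("plate_force", "proximal_force"):
            p1 = getattr(res1, attr).values.max()
            p2 = getattr(res2, attr).values.max()
            assert p1 == pytest.approx(p2, rel=0.01)

    def test_contact_compression_only(self, calibrated_chain):
        res = run(calibrated_chain, PulseSpec(5.2, 2e-3), dt=DT)
        assert res.plate_force.values.min() >= 0.0

    def test_causality_proximal_after_plate_onset(self, calibrated_chain):
        res = run(calibrated_chain, PulseSpec(5.2, 2e-3), dt=DT)
        onset = res.times[np.argmax(
            res.plate_force.values > 0.01 * res.plate_force.values.max())]
        t_peak, _ = peak(res.proximal_force)
        assert t_peak >= onset

    def test_dt_above_stability_limit_rejected(self):
        model = linear_chain(k_N_mm=1e4, masses=(1.0, 0.01))
        with pytest.raises(SimulationError, match="stability"):
            run(model, PulseSpec(1.0, 2e-3), dt=1e-3, duration=5e-3)

    def test_runtime_stiffening_instability_aborts(self):
        """dt stable for the initial tangent but not after a curve element
        stiffens 1000x triggers the in-loop stability abort."""
        curve = SpringCurve(((0, 0), (1.0, 10.0), (1.1, 10000.0)),
                            tension_only=False)
        elem = ChainElement.from_curve("hardening", 0, 1, curve,
                                       flag="compression")
        model = ChainModel([elem], [0.5, 0.05], ["plate", "m"],
                           boundary_mode="impactor")
        with pytest.raises(SimulationError, match="instability"):
            run(model, PendulumSpec(8.0, 0.5, 0.05), dt=5e-4, duration=0.5)


class TestFootCompression:
    def test_near_rigid_chain_negligible_compression(self):
        plantar = QLVParams(A=800.0, B=2.15, Q=0.0)  # 1000x stiffer tissue
        geometry = {"arch_stiffness_N_mm": 3e5, "ankle_stiffness_N_mm": 3e5,
                    "tibia_stiffness_N_mm": 3e5}
        model = build_limb_chain(plantar, SpringCurve.linear(234.6),
                                 geometry=geometry)
        res = run(model, PulseSpec(2.0, 2e-3), dt=5e-8)
        soft = build_limb_chain(QLVParams(A=0.8, B=2.15, Q=0.0),
                                SpringCurve.linear(234.6))
        res_soft = run(soft, PulseSpec(2.0, 2e-3), dt=DT)
        # "rigid" is asymptotic: a 1000x stiffer tissue stack still deflects
        # elastically under the (much larger) transmitted force
        assert res.foot_compression.values.max() < \
            0.25 * res_soft.foot_compression.values.max()

    def test_soft_heel_compresses_more_than_stiff(self):
        """A 10x stiffer heel produces strictly less peak compression."""
        soft = build_limb_chain(QLVParams(A=0.8, B=2.15, Q=1.6),
                                SpringCurve.linear(234.6))
        stiff = build_limb_chain(QLVParams(A=8.0, B=2.15, Q=1.6),
                                 SpringCurve.linear(234.6))
        spec = PulseSpec(5.0, 3e-3)
        c_soft = run(soft, spec, dt=DT).foot_compression.values.max()
        c_stiff = run(stiff, spec, dt=DT).foot_compression.values.max()
        assert c_stiff < c_soft

    def test_missing_ankle_node_rejected(self):
        model = linear_chain()
        res = run(model, PulseSpec(1.0, 2e-3), dt=DT, duration=5e-3)
        with pytest.raises(ValueError, match="ankle"):
            _ = res.foot_compression


class TestBoot:
    def test_layer_order_after_attachment(self, booted_chain):
        names = [e.name for e in booted_chain.elements[:4]]
        assert names == ["outsole", "midsole", "insole", "plantar"]
        # plantar now sits on top of the insole junction node
        assert booted_chain.elements[3].lo == 3
        assert booted_chain.boot_present

    def test_attachment_is_pure(self, calibrated_chain):
        n_elems = len(calibrated_chain.elements)
        n_nodes = calibrated_chain.n_nodes
        _ = attach_boot(calibrated_chain, cfg.default_boot_config())
        assert len(calibrated_chain.elements) == n_elems
        assert calibrated_chain.n_nodes == n_nodes
        assert not calibrated_chain.boot_present

    def test_double_attachment_rejected(self, booted_chain):
        with pytest.raises(ValueError, match="already"):
            attach_boot(booted_chain, cfg.default_boot_config())

    def test_boot_reduces_low_severity_peak_force(self, calibrated_chain,
                                                  booted_chain):
        spec = PulseSpec(5.0, 9e-3)
        f_u = run(calibrated_chain, spec, dt=DT).proximal_force.values.max()
        f_b = run(booted_chain, spec, dt=DT).proximal_force.values.max()
        assert f_b < f_u

    def test_empty_boot_rejected(self):
        with pytest.raises(ValueError):
            BootModel(layers=[])


class TestModelValidation:
    def test_bad_masses_rejected(self):
        with pytest.raises(ValueError):
            ChainModel([ChainElement.linear("s", 0, 1, 1.0)], [1.0, -1.0],
                       ["a", "b"])

    def test_unknown_boundary_mode_rejected(self):
        with pytest.raises(ValueError):
            ChainModel([ChainElement.linear("s", 0, 1, 1.0)], [1.0, 1.0],
                       ["a", "b"], boundary_mode="floating")

    def test_mode_input_mismatch_rejected(self, calibrated_chain,
                                          pendulum_chain):
        with pytest.raises(SimulationError):
            run(calibrated_chain, PendulumSpec(5.0, 23.0, 16.0), dt=DT)
        with pytest.raises(SimulationError):
            run(pendulum_chain, PulseSpec(5.0, 2e-3), dt=DT)
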