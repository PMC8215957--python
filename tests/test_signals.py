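import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ubblimb.signals import (FilterSpec, Signal, apply_filter,
                             integrate_to_velocity, peak, read_csv,
                             read_hdf5, resample, write_csv, write_hdf5)

FS = 25e3
DT = 1.0 / FS


def make(values, dt=DT, unit="N", t0=0.0):
    return Signal(t0, dt, np.asarray(values, dtype=float), unit=unit)


class TestSignalContainer:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Signal(0.0, -1e-5, np.zeros(10))
        with pytest.raises(ValueError):
            Signal(0.0, 1e-5, np.array([1.0]))
        with pytest.raises(ValueError):
            Signal(0.0, 1e-5, np.array([1.0, np.nan]))

    def test_time_base(self):
        s = make(np.zeros(5), dt=0.1, t0=1.0)
        assert np.allclose(s.times, [1.0, 1.1, 1.2, 1.3, 1.4])
        assert s.duration == pytest.approx(0.4)


class TestFiltering:
    @pytest.mark.parametrize("spec", [FilterSpec("CFC", 1000),
                                      FilterSpec("butterworth_lowpass", 1000)])
    def test_dc_passband_identity(self, spec):
        """A constant signal passes through with unit DC gain."""
        s = make(np.full(400, 7.0))
        out = apply_filter(s, spec)
        assert np.allclose(out.values, 7.0, atol=1e-9)
        assert out.n == s.n and out.t0 == s.t0 and out.dt == s.dt

    def test_all_zero_passthrough(self):
        s = make(np.zeros(400))
        assert np.allclose(apply_filter(s, FilterSpec("CFC", 1000)).values, 0)

    @pytest.mark.parametrize("spec", [FilterSpec("CFC", 1000),
                                      FilterSpec("butterworth_lowpass", 1000)])
    def test_stopband_attenuation_matches_fft_oracle(self, spec):
        """RMS attenuation of a 10x-cutoff sinusoid matches the filter's
        frequency response computed by DFT of its impulse response."""
        f_test = 10e3  # 10 x 1000 Hz at 25 kHz sampling
        n = 4096
        t = DT * np.arange(n)
        sine = make(np.sin(2 * np.pi * f_test * t))
        out = apply_filter(sine, spec)
        # discard edges where the finite record bites
        sl = slice(n // 4, 3 * n // 4)
        measured = (np.sqrt(np.mean(out.values[sl] ** 2))
                    / np.sqrt(np.mean(sine.values[sl] ** 2)))
        # oracle: |H(f)| from the impulse response
        imp = np.zeros(n)
        imp[n // 2] = 1.0
        h = apply_filter(make(imp), spec).values
        H = np.abs(np.fft.rfft(h))
        freqs = np.fft.rfftfreq(n, DT)
        gain = np.interp(f_test, freqs, H)
        assert measured == pytest.approx(gain, rel=0.05)
        assert measured < 0.2  # deep stop band at 10x cutoff

    @given(st.floats(min_value=-50, max_value=50).filter(lambda a: a != 0))
    def test_linearity_in_amplitude(self, a):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        spec = FilterSpec("CFC", 1000)
        y1 = apply_filter(make(a * x), spec).values
        y2 = a * apply_filter(make(x), spec).values
        assert np.allclose(y1, y2, rtol=1e-12, atol=1e-12)

    def test_cutoff_at_nyquist_rejected(self):
        s = make(np.zeros(400))
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filter(s, FilterSpec("butterworth_lowpass", 12500))
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filter(s, FilterSpec("CFC", 7000))

    def test_spec_parsing(self):
        assert FilterSpec.parse("cfc:1000") == FilterSpec("CFC", 1000)
        assert FilterSpec.parse("butter:500:4") == FilterSpec(
            "butterworth_lowpass", 500, 4)


class TestIntegration:
    def test_constant_acceleration(self):
        n = round(0.5 / DT) + 1
        a = make(np.full(n, 10.0), unit="m/s^2")
        v = integrate_to_velocity(a, v0=0.0)
        assert v.unit == "m/s"
        assert v.values[-1] == pytest.approx(10.0 * 0.5, rel=1e-9)

    def test_zero_acceleration_keeps_v0(self):
        a = make(np.zeros(100), unit="m/s^2")
        assert np.allclose(integrate_to_velocity(a, v0=1.2).values, 1.2)

    def test_non_acceleration_unit_rejected(self):
        with pytest.raises(ValueError, match="acceleration"):
            integrate_to_velocity(make(np.zeros(10), unit="N"))

    def test_triangular_pulse_closed_form(self):
        """Velocity of a symmetric triangular acceleration pulse equals the
        piecewise-quadratic antiderivative at every sample."""
        T = 10e-3
        n = 501
        dt = T / (n - 1)
        t = dt * np.arange(n)
        apk = 100.0
        acc = np.where(t <= T / 2, apk * t / (T / 2),
                       apk * (T - t) / (T / 2))
        v = integrate_to_velocity(make(acc, dt=dt, unit="m/s^2")).values
        v_exact = np.where(
            t <= T / 2,
            apk * t ** 2 / T,
            apk * T / 4 + 2 * apk * (t - T / 2)
            - apk * (t ** 2 - (T / 2) ** 2) / T)
        # trapezoid is exact to machine precision on piecewise-linear input
        assert np.allclose(v, v_exact, rtol=1e-9, atol=1e-12)

    def test_first_order_convergence(self):
        """Halving dt roughly quarters the trapezoidal error on a smooth
        (quadratic-error) integrand."""
        def err(n):
            dt = 1.0 / (n - 1)
            t = dt * np.arange(n)
            a = make(np.cos(2 * np.pi * t), dt=dt, unit="m/s^2")
            v = integrate_to_velocity(a).values
            v_exact = np.sin(2 * np.pi * t) / (2 * np.pi)
            return np.abs(v - v_exact).max()

        e1, e2 = err(101), err(201)
        assert e2 < 0.6 * e1  # strictly better than first order


class TestPeak:
    @pytest.mark.parametrize("vals,expected", [
        ([0, 3, 1], (1.0, 3.0)),
        ([2.0, 2.0, 2.0], (0.0, 2.0)),  # tie broken to earliest
    ])
    def test_examples(self, vals, expected):
        t, v = peak(make(vals, dt=1.0))
        assert (t, v) == expected

    def test_pulse_peak_location(self):
        from ubblimb.loading import PulseSpec, triangular_pulse
        sig = triangular_pulse(PulseSpec(5.0, 1.5e-3), dt=1e-5)
        t, v = peak(sig)
        assert t == pytest.approx(1.5e-3, abs=1e-5)
        assert v == pytest.approx(5.0)

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6),
                    min_size=2, max_size=60))
    def test_matches_brute_force_scan(self, vals):
        s = make(vals, dt=0.5, t0=-1.0)
        t, v = peak(s)
        best_t, best_v = None, -np.inf
        for i, x in enumerate(s.values):
            if x > best_v:
                best_t, best_v = s.t0 + i * s.dt, x
        assert v == best_v and t == best_t


class TestResample:
    def test_identity_at_own_dt(self):
        s = make(np.arange(10.0))
        out = resample(s, s.dt)
        assert np.allclose(out.values, s.values)

    def test_linear_ramp_exact(self):
        s = make(np.arange(10.0), dt=0.1)
        out = resample(s, 0.05)
        assert np.allclose(out.values, np.arange(0, 9.01, 0.5))

    def test_sinusoid_error_bound(self):
        """Linear interpolation error bounded by (dt^2/8) max|f''|."""
        f = 50.0
        dt = 1e-3
        t = dt * np.arange(200)
        s = make(np.sin(2 * np.pi * f * t), dt=dt)
        fine = resample(s, dt / 10)
        exact = np.sin(2 * np.pi * f * fine.times)
        bound = dt ** 2 / 8 * (2 * np.pi * f) ** 2
        assert np.abs(fine.values - exact).max() <= bound

    def test_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            resample(make(np.arange(5.0), dt=0.1), 1.0)


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        s = make(np.sin(np.arange(50)), dt=4e-5, unit="m/s^2")
        p = tmp_path / "sig.csv"
        write_csv(s, p)
        out = read_csv(p)
        assert out.unit == "m/s^2"
        assert out.dt == pytest.approx(s.dt)
        assert np.allclose(out.values, s.values, atol=1e-7)

    def test_hdf5_roundtrip(self, tmp_path):
        chans = {"force": make(np.arange(20.0), unit="N"),
                 "accel": make(np.ones(20), unit="m/s^2")}
        p = tmp_path / "run.h5"
        write_hdf5(p, chans)
        out = read_hdf5(p)
        assert set(out) == {"force", "accel"}
        assert np.allclose(out["force"].values, chans["force"].values)
        assert out["accel"].unit == "m/s^2"
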