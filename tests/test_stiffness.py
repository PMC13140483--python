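"""Foot detection, cfPWV, beta stiffness, impedance and wave separation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hemopulse as hp
from hemopulse.errors import DomainError, NoUpstrokeError, OrderingError
from hemopulse.stiffness import detect_foot


class TestDetectFoot:
    def test_flat_then_ramp_foot_is_exact(self):
        fs = 1000.0
        t0 = 0.2
        t = np.arange(600) / fs
        x = np.where(t < t0, 1.0, 1.0 + 5.0 * (t - t0))
        assert detect_foot(x, fs) == pytest.approx(t0, abs=1.5 / fs)

    def test_shift_equivariance(self, windkessel_beat):
        _, beat, _ = windkessel_beat
        fs = beat.sampling_rate
        shift = int(0.080 * fs)
        shifted = np.roll(beat.values, shift)
        d = detect_foot(shifted, fs) - detect_foot(beat.values, fs)
        assert d == pytest.approx(0.080, abs=1.0 / fs)

    def test_no_upstroke_errors(self):
        with pytest.raises(NoUpstrokeError):
            detect_foot(np.linspace(5, 0, 100), 100.0)

    def test_foot_jitter_under_noise(self, windkessel_beat):
        """At ~40 dB SNR the foot estimate scatters by < 2 ms."""
        _, beat, _ = windkessel_beat
        fs = beat.sampling_rate
        amp = beat.values.max() - beat.values.min()
        sigma = amp / 100.0  # 40 dB amplitude SNR
        rng = np.random.default_rng(42)
        feet = [
            detect_foot(beat.values + rng.normal(0, sigma, beat.values.size), fs)
            for _ in range(200)
        ]
        assert np.std(feet) < 0.002


class TestCfpwv:
    def _pair(self, pwv, distance=60.0, fs=1000.0, n_beats=8):
        params = hp.WindkesselParams(
            heart_rate=60, sampling_rate=fs, n_beats=n_beats)
        template, _ = hp.simulate_windkessel(params)
        prox, dist = hp.simulate_delayed_pair(template, distance, pwv)
        n = template.meta["samples_per_beat"]
        onsets = np.arange(0, n * n_beats + 1, n)[:n_beats]
        return prox, dist, hp.BeatSet(onsets, "r_wave", fs)

    def test_recovers_ground_truth_within_two_percent(self):
        prox, dist, beats = self._pair(750.0)
        res = hp.cfpwv(prox, dist, beats, 60.0)
        assert abs(res.cfpwv - 750.0) / 750.0 < 0.02
        assert res.transit_time == pytest.approx(0.08, abs=0.002)

    def test_simple_division(self):
        # delay of 0.1 s over 80 cm -> 800 cm/s
        prox, dist, beats = self._pair(pwv=800.0, distance=80.0)
        res = hp.cfpwv(prox, dist, beats, 80.0)
        assert res.cfpwv == pytest.approx(800.0, rel=0.02)

    def test_linear_in_path_distance(self):
        prox, dist, beats = self._pair(750.0)
        a = hp.cfpwv(prox, dist, beats, 60.0).cfpwv
        b = hp.cfpwv(prox, dist, beats, 120.0).cfpwv
        assert b == pytest.approx(2 * a)

    def test_zero_lag_raises_ordering_error(self):
        prox, _, beats = self._pair(750.0)
        with pytest.raises(OrderingError):
            hp.cfpwv(prox, prox, beats, 60.0)


class TestBetaStiffness:
    def test_printed_formula_worked_example(self):
        # 120/80 mmHg with 5.50 -> 6.05 mm distension: ln(1.5)/0.1
        assert hp.beta_stiffness(120, 80, 6.05, 5.50) == pytest.approx(
            np.log(1.5) / 0.1, abs=1e-12)

    def test_equal_pressures_give_zero(self):
        assert hp.beta_stiffness(100, 100, 6.0, 5.5) == 0.0

    @given(st.floats(1.01, 3.0), st.floats(40.0, 120.0),
           st.floats(0.01, 0.3), st.floats(4.0, 8.0),
           st.floats(1.1, 4.0))
    def test_pressure_ratio_invariance(self, ratio, p_dia, strain, d_dia, k):
        d_sys = d_dia * (1 + strain)
        a = hp.beta_stiffness(ratio * p_dia, p_dia, d_sys, d_dia)
        b = hp.beta_stiffness(k * ratio * p_dia, k * p_dia, d_sys, d_dia)
        assert a == pytest.approx(b, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            hp.beta_stiffness(120, 80, 5.5, 5.5)  # zero strain
        with pytest.raises(DomainError):
            hp.beta_stiffness(120, -1, 6.0, 5.5)


class TestVolumetricFlow:
    def test_area_and_unit_conversion(self):
        v = hp.SampledSignal(np.full(100, 40.0), 100.0, units="cm/s")
        flow = hp.volumetric_flow(v, 6.0)
        assert flow.cross_sectional_area == pytest.approx(0.2827, abs=1e-4)
        assert flow.values[0] == pytest.approx(11.31, abs=0.01)

    def test_zero_velocity_zero_flow(self):
        v = hp.SampledSignal(np.zeros(50), 100.0)
        assert np.all(hp.volumetric_flow(v, 5.0).values == 0)

    def test_flow_scales_with_area(self):
        v = hp.SampledSignal(np.full(50, 30.0), 100.0)
        a = hp.volumetric_flow(v, 6.0).values
        b = hp.volumetric_flow(v, 6.0 * np.sqrt(2)).values
        assert np.allclose(b, 2 * a)

    def test_nonpositive_diameter_errors(self):
        v = hp.SampledSignal(np.full(50, 30.0), 100.0)
        with pytest.raises(DomainError):
            hp.volumetric_flow(v, 0.0)


class TestCharacteristicImpedance:
    def test_proportional_waves_are_exact(self):
        t = np.arange(500) / 500.0
        q = 300 * np.sin(np.pi * t) ** 2
        p = hp.EnsembleBeat(0.1 * q + 80, 500.0, units="mmHg")
        fb = hp.FlowBeat(q, 500.0, 6.0, 0.28)
        assert hp.characteristic_impedance(p, fb) == pytest.approx(0.1)

    def test_windkessel_ground_truth_recovery(self, windkessel_beat):
        params, beat, fb = windkessel_beat
        zc = hp.characteristic_impedance(beat, fb)
        assert abs(zc - params.zc) / params.zc < 0.05

    def test_doubling_flow_halves_zc(self, windkessel_beat):
        _, beat, fb = windkessel_beat
        zc1 = hp.characteristic_impedance(beat, fb)
        fb2 = hp.FlowBeat(2 * fb.values, fb.sampling_rate, 6.0, 0.28)
        assert hp.characteristic_impedance(beat, fb2) == pytest.approx(
            zc1 / 2)

    def test_degenerate_flow_errors(self):
        p = hp.EnsembleBeat(80 + np.sin(np.arange(100) / 10.0), 100.0)
        fb = hp.FlowBeat(np.linspace(10, 0, 100), 100.0, 6.0, 0.28)
        with pytest.raises(DomainError):
            hp.characteristic_impedance(p, fb)


class TestWaveSeparation:
    def test_pure_forward_wave_has_zero_reflection(self):
        # triangular pulse: the tangent foot is exact on piecewise-linear
        # input and lands where Q = 0, so dP = Zc*dQ holds identically
        t = np.arange(500) / 500.0
        q = np.interp(t, [0.0, 0.1, 0.2, 0.5, 1.0], [0, 0, 300, 0, 0])
        p = hp.EnsembleBeat(80 + 0.1 * q, 500.0, units="mmHg")
        fb = hp.FlowBeat(q, 500.0, 6.0, 0.28)
        sep = hp.wave_separation(p, fb, 0.1)
        assert np.max(np.abs(sep.pb_wave)) < 1e-9
        assert sep.reflection_index == pytest.approx(0.0, abs=1e-12)

    def test_programmed_reflection_recovered(self):
        p, q = hp.simulate_pressure_with_reflection(zc=0.1, reflection=0.30)
        n = p.meta["samples_per_beat"]
        beat = hp.EnsembleBeat(p.values[:n], p.sampling_rate, units="mmHg")
        fb = hp.FlowBeat(q.values[:n], q.sampling_rate, 6.0, 0.28)
        sep = hp.wave_separation(beat, fb, 0.1)
        assert abs(sep.reflection_index - 0.30) / 0.30 < 0.10

    @given(st.integers(0, 2**31 - 1))
    def test_reconstruction_identity_holds_even_for_noise(self, seed):
        rng = np.random.default_rng(seed)
        p_vals = 80 + np.abs(rng.normal(0, 10, 300))
        p_vals[:20] = np.linspace(80, 81, 20)  # guarantee an upstroke
        q_vals = rng.normal(50, 30, 300)
        beat = hp.EnsembleBeat(p_vals, 300.0, units="mmHg")
        fb = hp.FlowBeat(q_vals, 300.0, 6.0, 0.28)
        sep = hp.wave_separation(beat, fb, float(rng.uniform(0.02, 0.5)))
        dp = beat.values - beat.values.min()
        assert np.max(np.abs(sep.pf_wave + sep.pb_wave - dp)) < 1e-9

    def test_nonpositive_zc_errors(self, windkessel_beat):
        _, beat, fb = windkessel_beat
        with pytest.raises(DomainError):
            hp.wave_separation(beat, fb, 0.0)
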