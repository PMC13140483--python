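"""Ground-truth generators: determinism, physics and round-trip contracts."""

import numpy as np
import pytest

import hemopulse as hp
from hemopulse.errors import InfeasibleTargetsError, InvalidParameterError


class TestWindkessel:
    def test_same_seed_is_bit_identical(self):
        p = hp.WindkesselParams(noise_sd=1.0, seed=9, n_beats=4)
        a_p, a_q = hp.simulate_windkessel(p)
        b_p, b_q = hp.simulate_windkessel(p)
        assert np.array_equal(a_p.values, b_p.values)
        assert np.array_equal(a_q.values, b_q.values)

    def test_steady_state_is_periodic(self):
        p = hp.WindkesselParams(heart_rate=53, sampling_rate=500, n_beats=3)
        pres, _ = hp.simulate_windkessel(p)
        n = pres.meta["samples_per_beat"]
        pp = pres.values[:n].max() - pres.values[:n].min()
        assert np.max(np.abs(pres.values[:n] - pres.values[n:2 * n])) < (
            1e-6 * pp)

    def test_diastolic_decay_time_constant(self):
        """With flow = 0 in diastole, pressure decays as exp(-t/(R*C))."""
        p = hp.WindkesselParams(r_peripheral=1.2, compliance=1.4,
                                sampling_rate=1000, n_beats=1)
        pres, flow = hp.simulate_windkessel(p)
        dia = slice(int(0.5 * 1000), int(0.95 * 1000))
        assert np.all(flow.values[dia] == 0)
        t = np.arange(pres.values[dia].size) / 1000.0
        tau = -1.0 / np.polyfit(t, np.log(pres.values[dia]), 1)[0]
        assert tau == pytest.approx(1.2 * 1.4, rel=1e-3)

    def test_flow_integrates_to_stroke_volume(self):
        p = hp.WindkesselParams(stroke_volume=70, heart_rate=60,
                                sampling_rate=1000, n_beats=1)
        _, flow = hp.simulate_windkessel(p)
        assert np.trapezoid(flow.values, dx=1e-3) == pytest.approx(70, rel=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            hp.WindkesselParams(zc=-0.1)
        with pytest.raises(InvalidParameterError):
            hp.WindkesselParams(ejection_fraction_of_cycle=1.2)
        with pytest.raises(InvalidParameterError):
            hp.WindkesselParams(sampling_rate=100)


class TestDelayedPair:
    def test_embedded_delay_arithmetic(self):
        t, _ = hp.simulate_windkessel(hp.WindkesselParams(n_beats=4))
        prox, dist = hp.simulate_delayed_pair(t, 60.0, 750.0)
        assert prox.meta["true_delay_s"] == pytest.approx(0.08)

    def test_infinite_pwv_limit_is_identity(self):
        t, _ = hp.simulate_windkessel(hp.WindkesselParams(n_beats=3))
        prox, dist = hp.simulate_delayed_pair(t, 60.0, 1e12)
        assert np.allclose(prox.values, dist.values, atol=1e-9)

    def test_delay_longer_than_cycle_rejected(self):
        t, _ = hp.simulate_windkessel(hp.WindkesselParams(n_beats=3))
        with pytest.raises(InvalidParameterError):
            hp.simulate_delayed_pair(t, 300.0, 100.0)  # 3 s delay


class TestDopplerEnvelope:
    def test_round_trip_beat_statistics(self):
        env = hp.simulate_doppler_envelope(98, 46, 63, heart_rate=60,
                                           duration_s=10, sampling_rate=200)
        n = int(200 * 1.0)
        beat = env.values[:n]
        assert abs(beat.max() - 98) / 98 < 0.005
        assert abs(beat.min() - 46) / 46 < 0.005
        assert abs(beat.mean() - 63) / 63 < 0.005

    def test_ordering_violations_named(self):
        with pytest.raises(InfeasibleTargetsError, match="v_dia < v_mean"):
            hp.simulate_doppler_envelope(60, 60, 60)
        with pytest.raises(InfeasibleTargetsError, match="v_mean < v_sys"):
            hp.simulate_doppler_envelope(70, 40, 75)

    def test_linearity_of_construction(self):
        a = hp.simulate_doppler_envelope(98, 46, 63, duration_s=5)
        b = hp.simulate_doppler_envelope(196, 92, 126, duration_s=5)
        assert np.allclose(b.values, 2 * a.values, rtol=1e-6)

    def test_unreachable_mean_rejected(self):
        # mean close to systolic needs a decay width beyond the beat
        with pytest.raises(InfeasibleTargetsError):
            hp.simulate_doppler_envelope(100, 40, 95)


class TestBreathHold:
    def test_schedule_arithmetic(self):
        _, _, sched = hp.simulate_breath_hold_session()
        assert sched.paced_s == pytest.approx(30.0)
        assert sched.n_repeats == 4

    def test_null_reactivity_mcav_flat(self):
        _, mcav, _ = hp.simulate_breath_hold_session(cvr_true=0.0)
        assert np.ptp(mcav.values) == 0.0

    def test_determinism(self):
        a = hp.simulate_breath_hold_session(noise_sd=0.5, seed=4)[0]
        b = hp.simulate_breath_hold_session(noise_sd=0.5, seed=4)[0]
        assert np.array_equal(a.values, b.values)


class TestCohort:
    CELLS = {"y": {("YA", "baseline"): (10.0, 2.0), ("YA", "30"): (12.0, 2.0),
                   ("YA", "60"): (11.0, 2.0), ("MA", "baseline"): (10.0, 2.0),
                   ("MA", "30"): (10.0, 2.0), ("MA", "60"): (10.0, 2.0)}}

    def test_zero_sd_reproduces_cell_means_exactly(self):
        cells = {
            "y": {k: (m, 0.0) for k, (m, _) in self.CELLS["y"].items()}
        }
        tab = hp.simulate_cohort(hp.CohortSpec(cells, n_per_group=5))
        for (g, tm), (m, _) in cells["y"].items():
            vals = tab[(tab.group == g) & (tab.time == tm)]["value"]
            assert np.all(vals == m)

    def test_within_subject_correlation_matches_request(self):
        cells = {"y": {(g, t): (0.0, 1.0) for g in ("YA", "MA")
                       for t in ("baseline", "30", "60")}}
        spec = hp.CohortSpec(cells, n_per_group=2000,
                             within_subject_correlation=0.8, seed=11)
        tab = hp.simulate_cohort(spec)
        wide = tab.pivot_table(index="subject", columns="time",
                               values="value")
        r = np.corrcoef(wide["baseline"], wide["30"])[0, 1]
        assert r == pytest.approx(0.8, abs=0.03)

    def test_marginal_moments_match_spec(self):
        spec = hp.CohortSpec(self.CELLS, n_per_group=4000, seed=21)
        tab = hp.simulate_cohort(spec)
        cell = tab[(tab.group == "YA") & (tab.time == "30")]["value"]
        assert cell.mean() == pytest.approx(12.0, abs=0.12)
        assert cell.std() == pytest.approx(2.0, abs=0.08)

    def test_times_restricted_to_protocol(self):
        with pytest.raises(InvalidParameterError):
            hp.CohortSpec(self.CELLS, n_per_group=5,
                          times=("baseline", "30", "90"))

    def test_determinism(self):
        spec = hp.CohortSpec(self.CELLS, n_per_group=10, seed=5)
        a = hp.simulate_cohort(spec)
        b = hp.simulate_cohort(spec)
        assert a.equals(b)
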