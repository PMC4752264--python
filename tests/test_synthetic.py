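"""Generator properties: determinism, rate calibration, planted structure."""

import numpy as np
import pytest

from penumbra import (
    HypoxiaProtocol,
    PhaseTimeline,
    ResponseKernel,
    StimulationSchedule,
    make_template,
    morph_template,
    render_raw_traces,
    simulate_spontaneous,
    simulate_stimulus_responses,
)
from penumbra.synthetic_mea import enforce_refractory

from conftest import make_ground_truth


class TestTemplates:
    def test_peak_position_and_amplitude(self):
        t = make_template(amplitude=50.0)
        assert len(t) == 96
        assert np.argmax(np.abs(t)) == 32
        assert np.max(np.abs(t)) == pytest.approx(50.0)

    def test_morph_widens_and_shrinks(self):
        t = make_template(amplitude=50.0)
        m = morph_template(t, 1.0)
        assert np.max(np.abs(m)) == pytest.approx(0.4 * 50.0)
        # widened: more mass away from the peak, relative to amplitude
        half = 0.5 * np.max(np.abs(m))
        assert np.sum(np.abs(m) > half) > np.sum(np.abs(t) > 0.5 * 50.0)
        np.testing.assert_array_equal(morph_template(t, 0.0), t)


class TestRefractory:
    def test_chained_violations_resolved_greedily(self):
        t = enforce_refractory(np.array([0.0, 0.0005, 0.001, 0.0016]), 1e-3)
        np.testing.assert_allclose(t, [0.0, 0.001])

    def test_clean_train_untouched(self):
        t = np.arange(10) * 0.01
        np.testing.assert_array_equal(enforce_refractory(t), t)


class TestSpontaneous:
    def test_determinism_byte_identical(self, normoxic_1h):
        gt = make_ground_truth(5, base_rate=2.0, seed=1)
        a = simulate_spontaneous(gt, normoxic_1h, seed=42)
        b = simulate_spontaneous(gt, normoxic_1h, seed=42)
        assert a.spikes.equals(b.spikes)
        np.testing.assert_array_equal(a.waveforms, b.waveforms)
        c = simulate_spontaneous(gt, normoxic_1h, seed=43)
        assert not a.spikes.equals(c.spikes)

    def test_uncoupled_counts_are_poisson_calibrated(self, normoxic_1h):
        """Zero coupling, normoxia: counts match base_rate within 3 SE
        aggregated over 20 seeded runs."""
        rate, T, n_units, n_runs = 2.0, 600.0, 4, 20
        gt = make_ground_truth(n_units, base_rate=rate, seed=2)
        total = 0
        for s in range(n_runs):
            rec = simulate_spontaneous(
                gt, normoxic_1h, duration_h=T / 3600.0, seed=s, with_waveforms=False
            )
            total += len(rec)
        mu = rate * T * n_units * n_runs
        assert abs(total - mu) < 3 * np.sqrt(mu)

    def test_planted_edge_lag(self, normoxic_1h):
        """A strong i->j edge at 5 ms: every j spike lags an i spike by ~5 ms."""
        adj = np.zeros((2, 2))
        adj[0, 1] = 1.0
        dly = np.zeros((2, 2))
        dly[0, 1] = 5.0
        gt = make_ground_truth(
            2, base_rate=[3.0, 1e-9], adjacency=adj, delay_ms=dly, seed=3
        )
        rec = simulate_spontaneous(gt, normoxic_1h, seed=7, with_waveforms=False)
        ti = rec.times(unit=0)
        tj = rec.times(unit=1)
        assert len(tj) > 100  # strength 1.0: j fires for almost every i spike
        lags = np.array([np.min(np.abs(t - (ti + 0.005))) for t in tj])
        assert np.all(lags < 1.5e-3)  # delay jitter is 0.2 ms

    def test_spike_annotation_and_sorting(self, normoxic_1h):
        gt = make_ground_truth(3, base_rate=1.0, seed=4)
        rec = simulate_spontaneous(gt, normoxic_1h, seed=8)
        t = rec.spikes["time_s"].to_numpy()
        assert np.all(np.diff(t) >= 0)
        assert set(rec.spikes["unit"]).issubset({0, 1, 2})
        np.testing.assert_array_equal(
            rec.spikes["electrode"], gt.unit_electrode[rec.spikes["unit"]]
        )

    def test_errors(self, normoxic_1h):
        gt = make_ground_truth(2)
        with pytest.raises(ValueError):
            simulate_spontaneous(gt, normoxic_1h, duration_h=0.0, seed=0)

    def test_silencing_onset_stops_unit(self):
        tl = PhaseTimeline.standard(1, 2, 0)
        prot = HypoxiaProtocol(tl, silencing_onset_h=np.array([1.5, np.inf]))
        gt = make_ground_truth(2, base_rate=2.0)
        rec = simulate_spontaneous(gt, prot, seed=9, with_waveforms=False)
        assert rec.times(unit=0).max() < 1.5 * 3600.0
        assert rec.times(unit=1).max() > 1.5 * 3600.0


class TestHypoxiaProtocol:
    def test_pO2_relaxation(self):
        prot = HypoxiaProtocol(PhaseTimeline.standard(2, 6, 3))
        assert prot.pO2(1.0) == pytest.approx(160.0)
        # one time constant into hypoxia
        expected = 23.0 + (160.0 - 23.0) * np.exp(-1.0)
        assert prot.pO2(2.95) == pytest.approx(expected)
        assert prot.pO2(7.9) == pytest.approx(23.0, abs=1.0)
        # recovery heads back up with tau_up
        assert 23.0 < prot.pO2(8.3) < 160.0
        assert prot.pO2(11.0) == pytest.approx(160.0, abs=2.0)

    def test_multipliers_bounded_and_baseline_unity(self):
        prot = HypoxiaProtocol(PhaseTimeline.standard(2, 6, 3), efficacy_min=0.5)
        t = np.linspace(0, 11, 500)
        eff = prot.efficacy(t)
        assert np.all((eff >= 0.5 - 1e-12) & (eff <= 1.0 + 1e-12))
        assert np.allclose(prot.efficacy(t[t < 2.0]), 1.0)

    def test_efficacy_halves_hypoxic_rates(self):
        """rate_curve tied to efficacy 0.5 suppresses activity below 50%+chance."""
        tl = PhaseTimeline.standard(1, 2, 0)
        prot = HypoxiaProtocol(tl, efficacy_min=0.5, tau_down_h=0.01)
        gt = make_ground_truth(10, base_rate=2.0, seed=5)
        rec = simulate_spontaneous(gt, prot, seed=10, with_waveforms=False)
        t_h = rec.spikes["time_s"].to_numpy() / 3600.0
        base = np.sum(t_h < 1.0)
        hyp = np.sum((t_h >= 1.5) & (t_h < 2.5))
        assert hyp / base < 0.6  # expected ratio 0.5 at zero coupling


class TestStimulusResponses:
    def _setup(self, late_total=10.0, n=6):
        tl = PhaseTimeline.standard(1, 0, 0)
        prot = HypoxiaProtocol(tl)
        gt = make_ground_truth(n, base_rate=1e-9)
        kern = ResponseKernel(
            early_prob=np.zeros((1, n)), late_mean=np.full((1, n), late_total / n)
        )
        sched = StimulationSchedule.hourly([0], tl, kernel=kern, seed=1)
        return gt, prot, sched

    def test_zero_kernel_identical_to_spontaneous(self, normoxic_1h):
        n = 4
        gt = make_ground_truth(n, base_rate=2.0, seed=6)
        kern = ResponseKernel(early_prob=np.zeros((1, n)), late_mean=np.zeros((1, n)))
        sched = StimulationSchedule.hourly([0], normoxic_1h.timeline, kernel=kern, seed=2)
        spont = simulate_spontaneous(gt, normoxic_1h, seed=11, with_waveforms=False)
        merged = simulate_stimulus_responses(
            gt, sched, normoxic_1h, seed=12, spontaneous=spont
        )
        assert merged.spikes["time_s"].tolist() == spont.spikes["time_s"].tolist()

    def test_late_counts_match_kernel(self):
        """Expected 10 late spikes/pulse at efficacy 1 -> counting oracle."""
        gt, prot, sched = self._setup(late_total=10.0)
        rec = simulate_stimulus_responses(
            gt,
            sched,
            prot,
            seed=13,
            spontaneous=simulate_spontaneous(gt, prot, seed=14, with_waveforms=False),
        )
        pulses = sched.pulse_times[0]
        t = rec.spikes["time_s"].to_numpy()
        per_pulse = [
            np.sum((t > t0 + 0.015) & (t < t0 + 0.150)) for t0 in pulses
        ]
        mean = np.mean(per_pulse)
        se = np.std(per_pulse, ddof=1) / np.sqrt(len(pulses))
        assert abs(mean - 10.0) < 3 * se + 0.2

    def test_schedule_outside_recording_rejected(self):
        gt, prot, _ = self._setup()
        bad = StimulationSchedule(
            [0],
            {0: np.array([5000.0])},
            kernel=ResponseKernel(np.zeros((1, 6)), np.zeros((1, 6))),
        )
        with pytest.raises(ValueError):
            simulate_stimulus_responses(
                gt,
                bad,
                prot,
                seed=15,
                spontaneous=simulate_spontaneous(gt, prot, seed=16, with_waveforms=False),
            )


class TestSchedule:
    def test_hourly_pulses_in_window_and_increasing(self):
        tl = PhaseTimeline.standard(2, 1, 0)
        sched = StimulationSchedule.hourly([3, 7], tl, seed=4)
        for e in (3, 7):
            t = sched.pulse_times[e]
            assert np.all(np.diff(t) > 0)
            assert np.all((t % 3600.0) < 600.0)
            assert len(t) > 0

    def test_ipi_within_range_per_hour(self):
        tl = PhaseTimeline.standard(1, 0, 0)
        sched = StimulationSchedule.hourly([0], tl, seed=5)
        t = sched.pulse_times[0]
        ipi = np.diff(t)
        assert np.all((ipi >= 5.0) & (ipi <= 10.0))


class TestRawTraces:
    @staticmethod
    def _short_timeline(seconds):
        from penumbra.timeline import Phase

        return PhaseTimeline([Phase("baseline", 0.0, seconds / 3600.0)], stim_minutes=0.0)

    def test_noise_only_statistics(self):
        from conftest import recording_from_arrays

        rec = recording_from_arrays([], [], timeline=self._short_timeline(10.0))
        traces = render_raw_traces(rec, noise_sd=2.0, seed=1, electrodes=[0])
        tr = traces[0]
        assert abs(np.mean(tr)) < 0.1
        assert abs(np.std(tr) - 2.0) < 0.1

    def test_single_spike_zero_noise_equals_template(self):
        gt = make_ground_truth(1, base_rate=1.0)
        from conftest import recording_from_arrays

        rec = recording_from_arrays(
            [1.0], [0], unit=[0], timeline=self._short_timeline(3.0), ground_truth=gt
        )
        traces = render_raw_traces(rec, noise_sd=0.0, seed=0, electrodes=[0])
        tr = traces[0]
        i = 16000 - 32
        np.testing.assert_allclose(tr[i : i + 96], gt.templates[0])
        assert np.all(tr[:i] == 0) and np.all(tr[i + 96 :] == 0)

    def test_negative_noise_rejected(self):
        from conftest import recording_from_arrays

        rec = recording_from_arrays([], [], timeline=self._short_timeline(2.0))
        with pytest.raises(ValueError):
            render_raw_traces(rec, noise_sd=-1.0)
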