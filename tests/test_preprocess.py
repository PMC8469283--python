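"""Preprocessing: spike extraction, ISI QC, envelopes, artifacts, steps."""

import numpy as np
import pytest

from cortemg.data import EMGTrace, GaitAnnotation, SpikeTrain
from cortemg.preprocess import (
    FormatError,
    ParameterError,
    apply_exclusions,
    consecutive_steps_stats,
    detect_artifacts,
    emg_envelope,
    extract_spike_events,
    filter_units_by_isi,
    segment_and_normalize,
)
from cortemg.synthetic import synthesize_raw_trace


FS_RAW = 40_000.0


class TestExtractSpikeEvents:
    def test_zero_trace_yields_no_events(self):
        train = extract_spike_events(np.zeros(4000), FS_RAW, 5.0)
        assert train.n_spikes == 0

    def test_single_injected_spike_detected_once(self):
        spike_t = 0.050
        trace = synthesize_raw_trace([spike_t], duration=0.2,
                                     sample_rate=FS_RAW, amplitude=10.0,
                                     seed=3)
        train = extract_spike_events(trace, FS_RAW, rms_multiplier=5.0)
        # oracle: scan the band-passed trace for sub-threshold excursions
        # separated by more than the lockout — exactly one region qualifies
        assert train.n_spikes == 1
        assert train.times[0] == pytest.approx(spike_t, abs=2e-3)

    def test_lower_threshold_detects_superset(self):
        rng = np.random.default_rng(7)
        trace = synthesize_raw_trace(
            np.arange(5) * 0.1 + 0.02, duration=0.6, sample_rate=FS_RAW,
            amplitude=8.0, seed=11) + 0.2 * rng.standard_normal(24000)
        low = extract_spike_events(trace, FS_RAW, 4.5).times
        high = extract_spike_events(trace, FS_RAW, 6.5).times
        assert len(low) >= len(high)
        for t in high:  # every strict event is also a loose event
            assert np.min(np.abs(low - t)) < 1.5e-3

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            extract_spike_events(np.zeros(1000), FS_RAW, 3.0)
        with pytest.raises(FormatError):
            extract_spike_events(np.zeros(1000), 10_000.0, 5.0)


class TestISIFilter:
    @staticmethod
    def _train_with_violation_fraction(frac: float, n_intervals: int = 100):
        """n_intervals ISIs of which round(frac * n) violate 1 ms."""
        n_bad = int(round(frac * n_intervals))
        isis = np.full(n_intervals, 0.010)
        isis[:n_bad] = 0.0005
        rng = np.random.default_rng(0)
        rng.shuffle(isis)
        return SpikeTrain(0, 0, np.cumsum(np.concatenate([[0.1], isis])))

    def test_two_percent_violations_pass(self):
        qc = filter_units_by_isi(self._train_with_violation_fraction(0.02))
        assert qc.isi_violation_fraction == pytest.approx(0.02)
        assert qc.passed

    def test_exactly_three_percent_fails_strict_inequality(self):
        qc = filter_units_by_isi(self._train_with_violation_fraction(0.03))
        assert qc.isi_violation_fraction == pytest.approx(0.03)
        assert not qc.passed

    def test_single_spike_train_passes_with_zero_fraction(self):
        qc = filter_units_by_isi(SpikeTrain(0, 0, np.array([1.0])))
        assert qc.isi_violation_fraction == 0.0
        assert qc.passed

    def test_invariance_under_translation_and_scaling(self):
        base = self._train_with_violation_fraction(0.02)
        shifted = SpikeTrain(0, 0, base.times + 17.3)
        scaled = SpikeTrain(0, 0, base.times * 2.0)
        f0 = filter_units_by_isi(base).isi_violation_fraction
        assert filter_units_by_isi(shifted).isi_violation_fraction == f0
        assert filter_units_by_isi(
            scaled, refractory_ms=2.0).isi_violation_fraction == f0

    def test_negative_refractory_raises(self):
        with pytest.raises(ParameterError):
            filter_units_by_isi(SpikeTrain(0, 0, np.array([0.1])), -1.0)


class TestEMGEnvelope:
    def test_constant_input_recovered(self):
        for c in (2.0, -2.0):
            trace = EMGTrace("LS", 1000.0, np.full(4000, c))
            env = emg_envelope(trace)
            mid = env.samples[1000:3000]
            assert np.allclose(mid, abs(c), rtol=1e-3)

    def test_rectified_sine_converges_to_two_over_pi(self):
        t = np.arange(8000) / 1000.0
        # the pi/20 phase keeps samples off the zero crossings, so the
        # discrete mean of the rectified wave stays at the analytic 2/pi
        trace = EMGTrace("LS", 1000.0,
                         np.sin(2 * np.pi * 100.0 * t + np.pi / 20))
        env = emg_envelope(trace)
        steady = env.samples[2000:6000]
        assert steady.mean() == pytest.approx(2 / np.pi, rel=0.01)

    def test_rectification_symmetry(self, rng):
        x = rng.standard_normal(3000)
        a = emg_envelope(EMGTrace("LS", 1000.0, x)).samples
        b = emg_envelope(EMGTrace("LS", 1000.0, -x)).samples
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_nonnegative_everywhere(self, rng):
        x = rng.standard_normal(3000)
        assert emg_envelope(EMGTrace("LS", 1000.0, x)).samples.min() >= 0.0

    def test_empty_trace_raises(self):
        with pytest.raises(FormatError):
            emg_envelope(EMGTrace("LS", 1000.0, np.array([])))


def _quiet_session_pieces(rng, n_units=4, duration=10.0):
    trains = [
        SpikeTrain(u, u, np.sort(rng.uniform(0, duration, 50)))
        for u in range(n_units)
    ]
    emg = [EMGTrace(m, 1000.0, 0.2 + 0.05 * rng.standard_normal(
        int(duration * 1000))) for m in ("LS", "RS")]
    return trains, emg


class TestDetectArtifacts:
    def test_quiet_recording_flags_nothing(self, rng):
        trains, emg = _quiet_session_pieces(rng)
        assert detect_artifacts(trains, emg, duration=10.0) == []

    def test_injected_simultaneous_spikes_flagged_once(self, rng):
        trains, emg = _quiet_session_pieces(rng)
        t_art = 5.0001
        trains = [
            SpikeTrain(t.unit_id, t.channel_id,
                       np.sort(np.append(t.times, t_art + 1e-5 * t.unit_id)))
            for t in trains
        ]
        intervals = detect_artifacts(trains, emg, duration=10.0)
        assert len(intervals) == 1
        lo, hi = intervals[0]
        assert lo <= t_art <= hi

    def test_large_emg_deflection_flagged_and_exclusion_idempotent(self, rng):
        from cortemg.data import GaitAnnotation, Session
        trains, emg = _quiet_session_pieces(rng, duration=20.0)
        emg[0].samples[7000:7200] += 30.0
        steps = np.array([[1.0 + i, 1.8 + i] for i in range(15)])
        session = Session("X", -7, 20.0, 0.4, trains, emg,
                          GaitAnnotation(steps, np.zeros(15, dtype=int)))
        intervals = detect_artifacts(trains, emg, duration=20.0)
        assert len(intervals) >= 1
        assert any(lo <= 7.1 <= hi for lo, hi in intervals)
        cleaned = apply_exclusions(session, intervals)
        again = detect_artifacts(cleaned.spike_trains, cleaned.emg_traces,
                                 duration=20.0)
        assert again == []
        # the step overlapping the artifact is gone, the rest survive
        assert cleaned.gait.n_steps == 14

    def test_channel_fraction_validated(self, rng):
        trains, emg = _quiet_session_pieces(rng)
        with pytest.raises(ParameterError):
            detect_artifacts(trains, emg, channel_fraction=0.0)


class TestSegmentAndNormalize:
    def test_row_count_and_length(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        gait = GaitAnnotation(np.array([[0.1, 0.137], [0.5, 1.4]]),
                              np.array([0, 0]))
        rows = segment_and_normalize(np.sin(t), t, gait, bins_per_step=100)
        assert rows.shape == (2, 100)

    def test_linear_ramp_endpoints_preserved(self):
        t = np.arange(1000) / 1000.0
        gait = GaitAnnotation(np.array([[0.2, 0.6]]), np.array([0]))
        rows = segment_and_normalize(t.copy(), t, gait, bins_per_step=50)
        assert rows[0, 0] == pytest.approx(0.2, abs=1e-9)
        assert rows[0, -1] == pytest.approx(0.6, abs=1e-9)

    def test_same_waveform_different_durations_give_identical_rows(self):
        fs = 1000.0
        # one cycle of a fixed waveform played over 0.8 s and over 1.2 s
        t = np.arange(int(2.5 * fs)) / fs
        signal = np.zeros_like(t)
        for start, dur in ((0.1, 0.8), (1.2, 1.2)):
            seg = (t >= start) & (t < start + dur)
            phase = (t[seg] - start) / dur
            signal[seg] = np.sin(2 * np.pi * phase) + 0.5 * phase
        gait = GaitAnnotation(np.array([[0.1, 0.9], [1.2, 2.4]]),
                              np.array([0, 1]))
        rows = segment_and_normalize(signal, t, gait, bins_per_step=80)
        np.testing.assert_allclose(rows[0], rows[1], atol=5e-3)

    def test_step_outside_support_raises(self):
        t = np.arange(100) / 1000.0
        gait = GaitAnnotation(np.array([[0.05, 0.2]]), np.array([0]))
        with pytest.raises(ValueError):
            segment_and_normalize(np.ones(100), t, gait, 10)


class TestConsecutiveSteps:
    @staticmethod
    def _gait(counts):
        steps, run_ids, t = [], [], 0.0
        for run, n in enumerate(counts):
            for _ in range(n):
                steps.append((t, t + 1.0))
                run_ids.append(run)
                t += 1.0
            t += 5.0
        return GaitAnnotation(np.array(steps), np.array(run_ids))

    def test_mean_and_total(self):
        stats = consecutive_steps_stats(self._gait([10, 5]))
        assert stats.mean == pytest.approx(7.5)
        assert stats.total == 15
        assert list(stats.per_run_counts) == [10, 5]

    def test_single_run_sd_zero(self):
        stats = consecutive_steps_stats(self._gait([8]))
        assert stats.sd == 0.0
        assert stats.mean == 8.0

    def test_empty_annotation_gives_zeros(self):
        stats = consecutive_steps_stats(
            GaitAnnotation(np.empty((0, 2)), np.empty(0, dtype=int)))
        assert stats.total == 0 and stats.mean == 0.0

    def test_generator_recovers_configured_run_length(self):
        # pre-lesion behaviour configured for ~85 consecutive steps per run
        from cortemg.synthetic import GeneratorConfig, simulate_session
        cfg = GeneratorConfig(seed=9, n_sessions=1, lesion_session=1,
                              session_duration=600.0, n_units_initial=2,
                              muscles=("LS",), artifact_rate=0.0,
                              steps_per_run_pre=85.0)
        stats = consecutive_steps_stats(simulate_session(cfg, 0).gait)
        # sampling error of a few Poisson(85) runs
        assert stats.mean == pytest.approx(85.0, rel=0.25)
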