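"""Eye pipeline: I-VT detection, windowed metrics, exclusions, baselines,
change rates and phase segmentation."""

import numpy as np
import pytest

from loadfatigue.eye import (
    GazeStream,
    SaccadeEvent,
    analysis_intervals,
    apply_exclusions,
    baseline_value,
    change_rate,
    detect_saccades,
    event_baseline,
    phase_means,
    phase_of_times,
    phase_segment,
    trial_change_rates,
    window_metrics,
)
from loadfatigue.simulate import GazeParams, generate_gaze


def _stream(az, el=None, rate=100.0, pupil=4.0, t0=0.0):
    az = np.asarray(az, dtype=float)
    n = az.size
    return GazeStream(
        timestamps=t0 + np.arange(n) / rate,
        azimuth=az,
        elevation=np.zeros(n) if el is None else np.asarray(el, float),
        pupil=np.full(n, pupil),
        validity=np.zeros(n, dtype=int),
        rate=rate,
    )


class TestDetectSaccades:
    def test_stationary_noise_yields_no_events(self, rng):
        az = rng.normal(0, 0.05, 2000)
        assert detect_saccades(_stream(az), 30.0, 0.01) == []

    def test_single_step_detected_with_full_amplitude(self):
        # 10 deg traversed at 200 deg/s -> 50 ms ramp
        rate, amp, speed = 100.0, 10.0, 200.0
        ramp = np.linspace(0, amp, int(amp / speed * rate) + 1)
        az = np.concatenate([np.zeros(100), ramp, np.full(100, amp)])
        events = detect_saccades(_stream(az, rate=rate), 30.0, 0.01)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(amp, rel=0.02)
        assert events[0].offset > events[0].onset

    def test_all_invalid_rejected(self):
        s = _stream(np.zeros(100))
        s.validity[:] = 1
        with pytest.raises(ValueError, match="no usable samples"):
            detect_saccades(s)

    @pytest.mark.parametrize("seed", range(5))
    def test_recall_precision_against_generator_truth(self, seed):
        stream, truth = generate_gaze(GazeParams(), 120.0, 100.0, seed)
        detected = detect_saccades(stream, 30.0, 0.01)
        t_truth = np.array([e.onset for e in truth])
        t_det = np.array([e.onset for e in detected])
        tol = 0.03
        recall = np.mean([(np.abs(t_det - t) < tol).any() for t in t_truth])
        precision = np.mean([(np.abs(t_truth - t) < tol).any() for t in t_det])
        assert recall >= 0.95
        assert precision >= 0.95


class TestWindowMetrics:
    def test_empty_window_keeps_pd(self):
        s = _stream(np.zeros(500), pupil=3.5)
        (w,) = window_metrics([], s, [(0.0, 5.0)])
        assert w.ST == 0
        assert np.isnan(w.SS) and np.isnan(w.SA)
        assert w.PD == pytest.approx(3.5)

    def test_amplitude_mean(self):
        events = [
            SaccadeEvent(onset=t, offset=t + 0.05, amplitude=a,
                         mean_speed=a / 0.05, peak_speed=2 * a / 0.05)
            for t, a in [(0.5, 2.0), (1.5, 4.0), (2.5, 6.0)]
        ]
        s = _stream(np.zeros(500))
        (w,) = window_metrics(events, s, [(0.0, 5.0)])
        assert w.ST == 3
        assert w.SA == pytest.approx(4.0)

    def test_tiling_windows_conserve_events(self, rng):
        stream, truth = generate_gaze(GazeParams(), 60.0, 100.0, 3)
        events = detect_saccades(stream)
        windows = [(-60.0 + 10.0 * k, -60.0 + 10.0 * (k + 1)) for k in range(18)]
        metrics = window_metrics(events, stream, windows)
        assert sum(m.ST for m in metrics) == len(events)


class TestExclusions:
    def test_five_minute_spacing_keeps_central_three_minutes(self):
        out = apply_exclusions([(300.0, 600.0)], [300.0, 600.0], 60.0)
        assert out == [(360.0, 540.0)]

    def test_zero_halfwidth_is_identity(self):
        wins = [(0.0, 300.0), (300.0, 600.0)]
        assert apply_exclusions(wins, [0.0, 300.0, 600.0], 0.0) == wins

    def test_dense_ratings_annihilate_everything(self):
        with pytest.warns(UserWarning, match="annihilated"):
            out = apply_exclusions(
                [(0.0, 120.0), (120.0, 240.0)], [0.0, 120.0, 240.0], 60.0
            )
        assert out == []

    def test_all_retained_intervals_are_180s(self):
        marks = [0.0, 300.0, 600.0, 900.0, 1200.0]
        intervals = analysis_intervals(marks, 60.0, 1200.0)
        assert len(intervals) == 4
        assert all(e - s == pytest.approx(180.0) for s, e in intervals)


class TestBaseline:
    def test_pooled_mean_of_pre_and_post(self):
        times = np.concatenate([np.arange(-60, 0, 1.0), np.arange(1201, 1261, 1.0)])
        values = np.concatenate([np.full(60, 4.0), np.full(60, 6.0)])
        assert baseline_value(values, times, 1200.0, 60.0) == pytest.approx(5.0)

    def test_constant_pre_post(self):
        times = np.concatenate([np.arange(-60, 0, 1.0), np.arange(1201, 1261, 1.0)])
        assert baseline_value(np.full(120, 3.0), times, 1200.0) == pytest.approx(3.0)

    def test_missing_post_segment_rejected(self):
        times = np.arange(-60, 0, 1.0)
        with pytest.raises(ValueError, match="baseline unavailable"):
            baseline_value(np.full(60, 3.0), times, 1200.0)

    def test_event_baseline_requires_both_segments(self):
        pre_only = [
            SaccadeEvent(-30.0, -29.95, 5.0, 100.0, 200.0),
            SaccadeEvent(-10.0, -9.95, 5.0, 100.0, 200.0),
        ]
        with pytest.raises(ValueError, match="baseline unavailable"):
            event_baseline(pre_only, 1200.0)


class TestChangeRate:
    def test_identity(self):
        assert change_rate(5.0, 5.0) == 0.0

    def test_arithmetic(self):
        assert change_rate(45.0, 50.0) == pytest.approx(-0.10)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="invalid baseline"):
            change_rate(1.0, 0.0)


class TestPhases:
    @pytest.mark.parametrize(
        "t, score, phase",
        [(3.0, 15.0, 1), (10.0, 25.0, 2), (18.0, 32.0, 3)],
    )
    def test_time_and_score_consistent(self, t, score, phase):
        assert phase_segment(t, score).phase == phase

    def test_score_mismatch_warns_but_labels_by_time(self):
        with pytest.warns(UserWarning, match="outside nominal bounds"):
            label = phase_segment(18.0, 25.0)
        assert label.phase == 3

    def test_out_of_trial_rejected(self):
        with pytest.raises(ValueError, match="out of trial"):
            phase_segment(25.0)

    def test_vectorised_labels_match_scalar(self):
        times = np.array([2.5, 5.0, 7.5, 12.5, 14.0, 17.5])
        assert list(phase_of_times(times)) == [
            phase_segment(t).phase for t in times
        ]


class TestTrialChangeRates:
    MARKS = [0.0, 300.0, 600.0, 900.0, 1200.0]

    def _averaged_phase_means(self, params, n_seeds=4):
        acc = {m: np.zeros(3) for m in ("ST", "SS", "SA", "PD")}
        for seed in range(n_seeds):
            stream, _ = generate_gaze(params, 1200.0, 100.0, seed)
            events = detect_saccades(stream)
            rates = trial_change_rates(stream, events, self.MARKS, 1200.0)
            for m in acc:
                pm = phase_means(rates[m])
                acc[m] += np.array([pm[1], pm[2], pm[3]])
        return {m: v / n_seeds for m, v in acc.items()}

    def test_monotone_amplitude_decline_gives_monotone_change_rates(self):
        params = GazeParams(
            saccade_amp_mean_by_phase=(4.9, 4.5, 4.0),
        )
        means = self._averaged_phase_means(params)
        assert means["SA"][0] > means["SA"][1] > means["SA"][2]
        assert means["SS"][0] > means["SS"][1] > means["SS"][2]

    def test_configured_phase_pattern_recovered(self):
        # saccade-count rebound in phase 3, monotone speed/amplitude decline
        params = GazeParams(
            fixation_rate_by_phase=(150.0 * 0.998, 150.0 * 0.927, 150.0 * 1.052),
            saccade_amp_mean_by_phase=(5 * 0.987, 5 * 0.926, 5 * 0.847),
            pupil_drift_by_phase=(0.02, 0.05, 0.08),
        )
        means = self._averaged_phase_means(params)
        st = means["ST"]
        assert st[2] > st[1] and st[2] > 0  # phase-3 rebound
        assert means["SA"][0] > means["SA"][1] > means["SA"][2] < 0
        assert means["PD"][2] > means["PD"][1] > means["PD"][0] > 0

    def test_flat_generator_gives_near_zero_change(self):
        means = self._averaged_phase_means(GazeParams(), n_seeds=3)
        for m in ("ST", "SS", "SA", "PD"):
            assert np.all(np.abs(means[m]) < 0.05)
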