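"""Gaze-stream analysis: I-VT saccade detection, windowed eye metrics,
baseline-relative change rates, and fatigue-phase segmentation.

Four metrics are tracked per analysis window: ST (saccade count), SS (mean
saccadic speed, deg/s), SA (mean saccadic amplitude, deg) and PD (mean pupil
diameter, mm).  Change rates are baseline-relative fractions
(Pt - P0) / P0 with P0 pooled from 60 s segments recorded immediately
before and after the walking bout.  The 20-min trial is segmented into
three perceptual-fatigue phases: 0-5 min, >5-14 min, >14-20 min,
nominally corresponding to overall-fatigue scores <20, 20-30, >30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Phase boundaries in minutes for the canonical 20-min trial.
PHASE_BOUNDS_MIN = (5.0, 14.0)
#: Overall-fatigue score bounds nominally separating the phases.
PHASE_SCORE_BOUNDS = (20.0, 30.0)


@dataclass
class GazeStream:
    """Monocular gaze angles (deg), pupil diameter (mm) and validity flags.

    ``validity`` follows the wearable-tracker convention: 0 = valid, >0 =
    tracking loss; invalid samples are excluded from every metric.
    """

    timestamps: np.ndarray
    azimuth: np.ndarray
    elevation: np.ndarray
    pupil: np.ndarray
    validity: np.ndarray
    rate: float = 100.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.azimuth = np.asarray(self.azimuth, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.validity = np.asarray(self.validity, dtype=int)
        n = self.timestamps.size
        for name in ("azimuth", "elevation", "pupil", "validity"):
            if getattr(self, name).size != n:
                raise ValueError("stream columns must have equal length")
        if n >= 2:
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValueError("unordered stream")
            implied = (n - 1) / (self.timestamps[-1] - self.timestamps[0])
            if abs(implied - self.rate) > 0.01 * self.rate:
                raise ValueError(
                    f"implied sampling rate {implied:.2f} Hz deviates >1% "
                    f"from declared {self.rate:.2f} Hz"
                )
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.validity == 0


@dataclass
class SaccadeEvent:
    """One detected (or generated) saccade."""

    onset: float
    offset: float
    amplitude: float     # deg, great-circle onset->offset displacement
    mean_speed: float    # deg/s, amplitude / duration
    peak_speed: float    # deg/s, max sample-to-sample angular speed

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EyeMetricWindow:
    window: tuple[float, float]
    ST: int
    SS: float   # nan when ST == 0
    SA: float   # nan when ST == 0
    PD: float


@dataclass
class ChangeRateSeries:
    """Baseline-relative change rates for one metric, one value per window."""

    metric_name: str
    t: np.ndarray              # window midpoints, minutes
    rate_of_change: np.ndarray  # fractions
    P0: float
    Pt: np.ndarray


def _unit_vectors(azimuth_deg: np.ndarray, elevation_deg: np.ndarray) -> np.ndarray:
    az = np.radians(azimuth_deg)
    el = np.radians(elevation_deg)
    return np.stack(
        [np.cos(el) * np.sin(az), np.sin(el), np.cos(el) * np.cos(az)], axis=-1
    )


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    dot = np.clip(np.sum(v1 * v2, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(dot))


def detect_saccades(
    stream: GazeStream,
    velocity_threshold: float = 30.0,
    min_duration: float = 0.01,
) -> list[SaccadeEvent]:
    """I-VT saccade detection.

    Angular speed is taken from central differences of valid gaze samples;
    maximal runs of super-threshold speed lasting at least ``min_duration``
    become events.  Amplitude is the great-circle angle between the gaze
    directions just before onset and just after offset, so the full
    displacement of the step is captured.  Events separated by less than one
    sample are merged.
    """
    if velocity_threshold <= 0:
        raise ValueError("velocity_threshold must be positive")
    valid = stream.valid_mask
    if valid.sum() < 2:
        raise ValueError("no usable samples")
    t = stream.timestamps[valid]
    vec = _unit_vectors(stream.azimuth[valid], stream.elevation[valid])

    speed = np.zeros(t.size)
    if t.size >= 3:
        speed[1:-1] = _angle_deg(vec[2:], vec[:-2]) / (t[2:] - t[:-2])
    speed[0] = _angle_deg(vec[1], vec[0]) / (t[1] - t[0])
    speed[-1] = _angle_deg(vec[-1], vec[-2]) / (t[-1] - t[-2])

    above = speed > velocity_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)

    # merge runs separated by less than one sample gap
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= 1:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_samples = max(1, int(np.ceil(min_duration * stream.rate)))
    events = []
    for s, e in merged:
        if e - s + 1 < min_samples:
            continue
        # the event covers the last super-threshold sample's interval too;
        # without this the quantised duration underestimates saccade time
        # and biases mean speed upward for small saccades
        onset = t[s]
        offset = t[e + 1] if e + 1 < t.size else t[e] + 1.0 / stream.rate
        i0, i1 = max(s - 1, 0), min(e + 1, t.size - 1)
        amplitude = float(_angle_deg(vec[i0][None], vec[i1][None])[0])
        if amplitude <= 0 or offset <= onset:
            continue
        events.append(
            SaccadeEvent(
                onset=float(onset),
                offset=float(offset),
                amplitude=amplitude,
                mean_speed=amplitude / (offset - onset),
                peak_speed=float(speed[s : e + 1].max()),
            )
        )
    return events


def window_metrics(
    events: list[SaccadeEvent],
    stream: GazeStream,
    windows: list[tuple[float, float]],
) -> list[EyeMetricWindow]:
    """Per-window ST/SS/SA/PD.  Events are assigned by onset time; a window's
    SS and SA are NaN when it contains no events."""
    onsets = np.array([ev.onset for ev in events])
    valid = stream.valid_mask
    out = []
    for start, end in windows:
        in_win = (
            (onsets >= start) & (onsets < end) if onsets.size else np.zeros(0, bool)
        )
        idx = np.where(in_win)[0]
        pd_mask = valid & (stream.timestamps >= start) & (stream.timestamps < end)
        pd_mean = float(np.mean(stream.pupil[pd_mask])) if pd_mask.any() else np.nan
        if idx.size:
            ss = float(np.mean([events[i].mean_speed for i in idx]))
            sa = float(np.mean([events[i].amplitude for i in idx]))
        else:
            ss = sa = np.nan
        out.append(EyeMetricWindow((start, end), int(idx.size), ss, sa, pd_mean))
    return out


def apply_exclusions(
    windows: list[tuple[float, float]],
    rating_times: list[float],
    halfwidth: float = 60.0,
) -> list[tuple[float, float]]:
    """Remove +-halfwidth zones around each self-rating from the windows.

    With the study's 5-min rating spacing and 60 s half-width, each
    inter-rating gap shrinks to its central 3 min.  Windows annihilated by
    overlapping exclusions are dropped with a warning.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be non-negative")
    retained = []
    for start, end in windows:
        pieces = [(start, end)]
        for rt in rating_times:
            lo, hi = rt - halfwidth, rt + halfwidth
            pieces = [
                piece
                for s, e in pieces
                for piece in ((s, min(e, lo)), (max(s, hi), e))
                if piece[1] - piece[0] > 0
            ]
        if not pieces:
            warnings.warn(
                f"window [{start}, {end}] annihilated by rating exclusions",
                stacklevel=2,
            )
        retained.extend(pieces)
    return retained


def analysis_intervals(
    rating_times: list[float], halfwidth: float, duration: float
) -> list[tuple[float, float]]:
    """Retained analysis intervals between consecutive self-ratings."""
    marks = sorted(rating_times)
    gaps = list(zip(marks[:-1], marks[1:]))
    if not gaps:
        gaps = [(0.0, duration)]
    return apply_exclusions(gaps, marks, halfwidth)


def baseline_value(
    values: np.ndarray,
    times: np.ndarray,
    trial_duration: float,
    baseline_window: float = 60.0,
) -> float:
    """Pooled baseline P0: the mean of a sampled metric over the pre-trial
    [-W, 0) and post-trial (D, D+W] segments."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    pre = (times >= -baseline_window) & (times < 0)
    post = (times > trial_duration) & (times <= trial_duration + baseline_window)
    if not pre.any() or not post.any():
        raise ValueError("baseline unavailable")
    return float(np.mean(np.concatenate([values[pre], values[post]])))


def event_baseline(
    events: list[SaccadeEvent],
    trial_duration: float,
    baseline_window: float = 60.0,
) -> dict[str, float]:
    """Baseline ST-rate (events/min), SS and SA pooled over pre+post segments."""
    pre = [e for e in events if -baseline_window <= e.onset < 0]
    post = [e for e in events if trial_duration < e.onset <= trial_duration + baseline_window]
    if not pre or not post:
        raise ValueError("baseline unavailable")
    both = pre + post
    total_min = 2 * baseline_window / 60.0
    return {
        "ST": len(both) / total_min,
        "SS": float(np.mean([e.mean_speed for e in both])),
        "SA": float(np.mean([e.amplitude for e in both])),
    }


def change_rate(Pt, P0: float):
    """Baseline-relative rate of change (Pt - P0) / P0 as a fraction."""
    if P0 <= 0:
        raise ValueError("invalid baseline")
    return (np.asarray(Pt, dtype=float) - P0) / P0


@dataclass
class PhaseLabel:
    phase: int
    time_bounds: tuple[float, float]       # minutes
    score_bounds: tuple[float, float]      # overall-fatigue interval


_PHASES = {
    1: ((0.0, PHASE_BOUNDS_MIN[0]), (-np.inf, PHASE_SCORE_BOUNDS[0])),
    2: ((PHASE_BOUNDS_MIN[0], PHASE_BOUNDS_MIN[1]), PHASE_SCORE_BOUNDS),
    3: ((PHASE_BOUNDS_MIN[1], 20.0), (PHASE_SCORE_BOUNDS[1], np.inf)),
}


def phase_segment(time_min: float, score: float | None = None) -> PhaseLabel:
    """Label an analysis time (minutes) with its fatigue phase (1/2/3).

    Phases are time-binned (0-5, >5-14, >14-20 min); when an overall-fatigue
    score is supplied it is checked against the phase's nominal score bounds
    and a mismatch emits a warning rather than an error, since low-fatigue
    conditions legitimately never reach the upper scores.
    """
    if time_min < 0 or time_min > 20:
        raise ValueError("out of trial")
    for phase, (tb, sb) in _PHASES.items():
        if time_min <= tb[1] or phase == 3:
            if score is not None and not (sb[0] <= score <= sb[1]):
                warnings.warn(
                    f"overall score {score} outside nominal bounds {sb} "
                    f"for phase {phase}",
                    stacklevel=2,
                )
            return PhaseLabel(phase=phase, time_bounds=tb, score_bounds=sb)
    raise AssertionError("unreachable")


def phase_of_times(times_min: np.ndarray) -> np.ndarray:
    """Vectorised phase labels for an array of analysis times (minutes)."""
    times_min = np.asarray(times_min, dtype=float)
    return np.digitize(times_min, PHASE_BOUNDS_MIN, right=True) + 1


def trial_change_rates(
    stream: GazeStream,
    events: list[SaccadeEvent],
    rating_times: list[float],
    trial_duration: float = 1200.0,
    halfwidth: float = 60.0,
    baseline_window: float = 60.0,
) -> dict[str, ChangeRateSeries]:
    """End-to-end change-rate extraction for one trial.

    Computes ST/SS/SA/PD per retained 3-min inter-rating interval, converts
    ST to a per-minute rate, and normalises each metric by its pooled
    pre/post baseline.  Returns one ChangeRateSeries per metric.
    """
    intervals = analysis_intervals(rating_times, halfwidth, trial_duration)
    metrics = window_metrics(events, stream, intervals)
    base = event_baseline(events, trial_duration, baseline_window)
    pd0 = baseline_value(
        stream.pupil[stream.valid_mask],
        stream.timestamps[stream.valid_mask],
        trial_duration,
        baseline_window,
    )
    mids = np.array([(s + e) / 2 / 60.0 for s, e in intervals])
    per_metric: dict[str, ChangeRateSeries] = {}
    series = {
        "ST": np.array(
            [m.ST / ((m.window[1] - m.window[0]) / 60.0) for m in metrics]
        ),
        "SS": np.array([m.SS for m in metrics]),
        "SA": np.array([m.SA for m in metrics]),
        "PD": np.array([m.PD for m in metrics]),
    }
    baselines = {**base, "PD": pd0}
    for name, pt in series.items():
        per_metric[name] = ChangeRateSeries(
            metric_name=name,
            t=mids,
            rate_of_change=change_rate(pt, baselines[name]),
            P0=baselines[name],
            Pt=pt,
        )
    return per_metric


def phase_means(series: ChangeRateSeries) -> dict[int, float]:
    """Mean change rate per fatigue phase, ignoring NaN windows."""
    phases = phase_of_times(series.t)
    out = {}
    for ph in (1, 2, 3):
        vals = series.rate_of_change[phases == ph]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[ph] = float(np.mean(vals))
    return out
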