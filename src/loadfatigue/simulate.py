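"""Synthetic trial generation for the load-carriage fatigue design.

Every generator is a pure function of (params, seed).  A trial consists of
a 20-min walking bout flanked by 60 s pre/post baseline segments:

* EMG: band-limited Gaussian carrier (the 20-450 Hz muscle-activation band)
  amplitude-modulated by a linear fatigue envelope, plus white Gaussian
  sensor noise and a low-frequency sinusoidal motion artifact.  Calibration
  is *through the denoising pipeline*: a universal-family soft threshold
  removes nearly all Gaussian-distributed detail energy, so the generator
  measures the pipeline's scale-free attenuation on a unit-amplitude pilot
  record and divides the target amplitudes by it (see docs/methods.md).
* Gaze: alternating fixations (Gaussian positional noise) and ballistic
  saccades following a linear main sequence (peak speed = slope x
  amplitude, raised-cosine profile), with per-phase saccade rates and
  amplitudes applied on the fatigue-phase boundaries; pupil diameter drifts
  upward per phase.  The ground-truth event list is returned alongside the
  stream.
* Ratings: piecewise-linear VAS and overall-fatigue trajectories at the
  5-min marks plus truncated Gaussian noise, clipped to scale bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sig

from . import calibration as cal
from .config import RunConfig
from .emg import CHANNEL_LABELS, EMGSignal, WaveletConfig, wtd_denoise
from .eye import GazeStream, SaccadeEvent
from .io import TrialCondition, TrialRecord
from .ratings import OVERALL_MAX, OVERALL_MIN, VAS_SITES, RatingSeries

#: Walking-bout phase boundaries as fractions of the bout duration
#: (5/20 and 14/20 of the canonical 20-min trial).
PHASE_FRACTIONS = (0.25, 0.70)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class EMGChannelParams:
    """Raw-signal parameters for one EMG channel (amplitudes in uV,
    expressed as rectified-mean envelope levels)."""

    base_amplitude: float
    end_amplitude: float
    band: tuple[float, float] = (20.0, 450.0)
    noise_sd: float = 0.0
    artifact_amplitude: float = 0.0
    artifact_freq: float = 1.2

    def __post_init__(self) -> None:
        if self.base_amplitude < 0 or self.end_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.artifact_amplitude and self.artifact_freq >= self.band[0]:
            raise ValueError("artifact_freq must lie below the passband")


@dataclass
class GazeParams:
    """Saccade/fixation/pupil generator parameters.

    Rates are saccades/min and amplitudes degrees; the ``*_by_phase``
    vectors (length 3) apply within the walking bout, the ``baseline_*``
    values within the pre/post rest segments."""

    baseline_rate: float = 150.0
    fixation_rate_by_phase: tuple[float, float, float] = (150.0, 150.0, 150.0)
    baseline_amplitude: float = 5.0
    saccade_amp_mean_by_phase: tuple[float, float, float] = (5.0, 5.0, 5.0)
    main_sequence_slope: float = 40.0        # peak deg/s per deg amplitude
    pupil_baseline: float = 4.0              # mm
    pupil_drift_by_phase: tuple[float, float, float] = (0.0, 0.0, 0.0)  # fractions
    fixation_noise_sd: float = 0.05          # deg
    pupil_noise_sd: float = 0.05             # mm
    amp_spread: float = 0.15                 # relative amplitude jitter
    min_amplitude: float = 2.0               # deg
    refractory: float = 0.15                 # s minimum fixation duration
    field_halfwidth: float = 15.0            # deg gaze-box half width

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "baseline_amplitude",
                     "main_sequence_slope", "pupil_baseline"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fixation_rate_by_phase", "saccade_amp_mean_by_phase",
                     "pupil_drift_by_phase"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"{name} must have length 3")


@dataclass
class RatingParams:
    """Rating-trajectory parameters: values at the 5-min marks."""

    overall_marks: np.ndarray = field(
        default_factory=lambda: cal.DEFAULT_OVERALL_MARKS.copy()
    )
    vas_start_by_site: dict[str, float] = field(
        default_factory=lambda: {"shoulder": 3.5, "back": 2.0, "waist": 2.0}
    )
    vas_growth_by_site: dict[str, float] = field(
        default_factory=lambda: {"shoulder": 0.6, "back": 0.5, "waist": 0.5}
    )
    rating_noise_sd: float = 0.3
    require_phase_crossings: bool = False

    def __post_init__(self) -> None:
        self.overall_marks = np.asarray(self.overall_marks, dtype=float)
        if self.require_phase_crossings and not self.crosses_phase_bounds():
            raise ValueError(
                "overall trajectory must cross scores 20 and 30 within the trial"
            )

    def crosses_phase_bounds(self) -> bool:
        m = self.overall_marks
        return bool(m.min() < 20 and m.max() > 30)


@dataclass
class TrialCalibration:
    """Per-condition generator parameters for one design cell."""

    emg: dict[str, EMGChannelParams]
    gaze: GazeParams
    ratings: RatingParams


# ---------------------------------------------------------------------------
# EMG generation
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_emg(
    params: EMGChannelParams,
    duration: float,
    rate: float,
    seed,
    channel_label: str = "M1",
) -> EMGSignal:
    """Synthesise one EMG channel: enveloped band-limited carrier + white
    noise + low-frequency artifact.  Pure function of (params, seed)."""
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    lo, hi = params.band
    nyq = rate / 2
    if not 0 < lo < hi < nyq:
        raise ValueError("invalid band")
    rng = _as_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    envelope = np.linspace(params.base_amplitude, params.end_amplitude, n)
    if envelope.any():
        white = rng.standard_normal(n)
        sos = sig.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
        carrier = sig.sosfiltfilt(sos, white)
        # unit rectified-mean normalisation so the envelope IS the iEMG level
        carrier *= np.sqrt(np.pi / 2.0) / carrier.std()
        x = envelope * carrier
    else:
        rng.standard_normal(n)  # keep the stream position seed-stable
        x = np.zeros(n)
    if params.noise_sd > 0:
        x = x + params.noise_sd * rng.standard_normal(n)
    if params.artifact_amplitude > 0:
        x = x + params.artifact_amplitude * np.sin(
            2 * np.pi * params.artifact_freq * t
        )
    return EMGSignal(x, rate, channel_label)


_GAIN_CACHE: dict[tuple, float] = {}
_PILOT_SAMPLES = 2**17
_PILOT_SEED = 987654321


def pipeline_gain(
    params: EMGChannelParams,
    n_target: int,
    rate: float,
    wavelet: WaveletConfig | None = None,
) -> float:
    """Scale-free attenuation of the denoise+iEMG pipeline for this channel
    shape (band, relative noise/artifact), measured on a unit-amplitude pilot.

    The LSMU rule is scale-equivariant, so the gain is independent of the
    absolute amplitude; ``n_target`` enters through the threshold's ln(N).
    Deterministic (fixed internal pilot seed) and cached.
    """
    wavelet = wavelet or WaveletConfig()
    amp = (params.base_amplitude + params.end_amplitude) / 2.0
    if amp <= 0:
        raise ValueError("gain undefined for a zero-amplitude channel")
    key = (
        params.band,
        round(params.noise_sd / amp, 9),
        round(params.artifact_amplitude / amp, 9),
        params.artifact_freq,
        n_target,
        rate,
        wavelet.wavelet_name,
        wavelet.level,
        wavelet.sigma_estimator,
    )
    if key not in _GAIN_CACHE:
        unit = EMGChannelParams(
            base_amplitude=1.0,
            end_amplitude=1.0,
            band=params.band,
            noise_sd=params.noise_sd / amp,
            artifact_amplitude=params.artifact_amplitude / amp,
            artifact_freq=params.artifact_freq,
        )
        pilot = generate_emg(
            unit, _PILOT_SAMPLES / rate, rate, np.random.default_rng(_PILOT_SEED)
        )
        denoised, _ = wtd_denoise(pilot, wavelet, threshold_length=n_target)
        _GAIN_CACHE[key] = float(np.mean(np.abs(denoised.samples)))
    return _GAIN_CACHE[key]


# ---------------------------------------------------------------------------
# gaze generation
# ---------------------------------------------------------------------------


def _phase_edges(duration: float) -> tuple[float, float]:
    return duration * PHASE_FRACTIONS[0], duration * PHASE_FRACTIONS[1]


def _segment_params(params: GazeParams, duration: float):
    """(start, end, rate, amplitude, pupil factor) per generation segment."""
    e1, e2 = _phase_edges(duration)
    segs = [(-np.inf, 0.0, params.baseline_rate, params.baseline_amplitude, 0.0)]
    bounds = [(0.0, e1), (e1, e2), (e2, duration)]
    for (s, e), r, a, d in zip(
        bounds,
        params.fixation_rate_by_phase,
        params.saccade_amp_mean_by_phase,
        params.pupil_drift_by_phase,
    ):
        segs.append((s, e, r, a, d))
    segs.append((duration, np.inf, params.baseline_rate, params.baseline_amplitude, 0.0))
    return segs


def generate_gaze(
    params: GazeParams,
    duration: float,
    rate: float,
    seed,
    baseline_window: float = 60.0,
) -> tuple[GazeStream, list[SaccadeEvent]]:
    """Synthesise a gaze stream spanning [-baseline, duration + baseline].

    Returns the stream and the ground-truth saccade event list.  Pre/post
    baseline segments use the baseline rate/amplitude (rest), the walking
    bout the per-phase values.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = _as_rng(seed)
    t0, t1 = -baseline_window, duration + baseline_window
    n = int(round((t1 - t0) * rate)) + 1
    times = t0 + np.arange(n) / rate

    segs = _segment_params(params, duration)

    def seg_of(t: float):
        for s in segs:
            if s[0] <= t < s[1]:
                return s
        return segs[-1]

    az = np.empty(n)
    el = np.empty(n)
    events: list[SaccadeEvent] = []
    pos = np.zeros(2)
    cursor = t0
    idx = 0

    def fill_fixation(until: float, p: np.ndarray) -> int:
        nonlocal idx
        stop = np.searchsorted(times, until, side="left")
        az[idx:stop] = p[0]
        el[idx:stop] = p[1]
        idx = stop
        return stop

    while cursor < t1:
        s = seg_of(cursor)
        seg_rate = s[2]
        if seg_rate <= 0:
            nxt = min(s[1], t1)
            fill_fixation(nxt, pos)
            cursor = nxt
            continue
        amp_mean = s[3]
        d = np.pi / (2.0 * params.main_sequence_slope)  # saccade duration, s
        mean_gap = max(60.0 / seg_rate - params.refractory - d, 0.01)
        wait = params.refractory + rng.exponential(mean_gap)
        onset = cursor + wait
        if onset + d >= min(s[1], t1):
            nxt = min(s[1], t1)
            fill_fixation(nxt, pos)
            cursor = nxt
            continue
        amp = rng.normal(amp_mean, params.amp_spread * amp_mean)
        amp = float(np.clip(amp, params.min_amplitude, params.field_halfwidth))
        theta = rng.uniform(0, 2 * np.pi)
        target = pos + amp * np.array([np.cos(theta), np.sin(theta)])
        if np.abs(target).max() > params.field_halfwidth:
            # re-aim toward centre to stay inside the gaze box
            direction = -pos / (np.linalg.norm(pos) or 1.0)
            target = pos + amp * direction
        fill_fixation(onset, pos)
        stop = np.searchsorted(times, onset + d, side="left")
        tau = (times[idx:stop] - onset) / d
        prog = 0.5 * (1 - np.cos(np.pi * np.clip(tau, 0, 1)))
        az[idx:stop] = pos[0] + (target[0] - pos[0]) * prog
        el[idx:stop] = pos[1] + (target[1] - pos[1]) * prog
        idx = stop
        events.append(
            SaccadeEvent(
                onset=float(onset),
                offset=float(onset + d),
                amplitude=amp,
                mean_speed=amp / d,
                peak_speed=params.main_sequence_slope * amp,
            )
        )
        pos = target
        cursor = onset + d
    fill_fixation(t1 + 1.0, pos)

    az += rng.normal(0, params.fixation_noise_sd, n)
    el += rng.normal(0, params.fixation_noise_sd, n)

    drift = np.zeros(n)
    for s in segs:
        mask = (times >= s[0]) & (times < s[1])
        drift[mask] = s[4]
    pupil = params.pupil_baseline * (1.0 + drift)
    pupil += 0.01 * np.sin(2 * np.pi * 0.05 * (times - t0))  # slow fluctuation
    pupil += rng.normal(0, params.pupil_noise_sd, n)
    pupil = np.maximum(pupil, 0.5)

    stream = GazeStream(
        timestamps=times,
        azimuth=az,
        elevation=el,
        pupil=pupil,
        validity=np.zeros(n, dtype=int),
        rate=rate,
    )
    return stream, events


# ---------------------------------------------------------------------------
# ratings generation
# ---------------------------------------------------------------------------


def generate_ratings(
    params: RatingParams,
    seed,
    times_min: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0),
) -> RatingSeries:
    """Self-ratings at the 5-min marks with truncated Gaussian noise."""
    rng = _as_rng(seed)
    t = np.asarray(times_min, dtype=float)
    steps = t / 5.0
    vas = {}
    for site in VAS_SITES:
        base = params.vas_start_by_site[site] + params.vas_growth_by_site[site] * steps
        noisy = base + rng.normal(0, params.rating_noise_sd, t.size)
        vas[site] = np.clip(noisy, 0.0, 10.0)
    marks = np.interp(t, np.linspace(0, 20, params.overall_marks.size),
                      params.overall_marks)
    overall = np.clip(
        marks + rng.normal(0, params.rating_noise_sd, t.size),
        OVERALL_MIN,
        OVERALL_MAX,
    )
    return RatingSeries(times=t, vas=vas, overall=overall)


# ---------------------------------------------------------------------------
# condition-level calibration and full trials
# ---------------------------------------------------------------------------


def study_calibration(
    condition: TrialCondition,
    duration: float = 1200.0,
    config: RunConfig | None = None,
    noise_ratio: float = 0.05,
    artifact_ratio: float = 0.05,
    ramp: float = 0.10,
) -> TrialCalibration:
    """Generator parameters calibrated to the study's condition-level means.

    EMG amplitudes are divided by the measured pipeline gain so that the
    denoise+iEMG chain reproduces each channel's target mean; eye-metric
    phase profiles follow the published phase trends shifted (saccades) or
    scaled (pupil) to the condition's trial mean; rating trajectories are
    shifted to the condition's overall-fatigue mean.
    """
    config = config or RunConfig()
    lt, slope = condition.loading_type.value, condition.slope.value
    wavelet = WaveletConfig(config.wavelet_name, config.decomposition_level)
    n_target = int(round(duration * config.emg_sampling_rate))

    emg_params = {}
    for ch in CHANNEL_LABELS:
        target = cal.iemg_target(ch, lt, slope)
        shape = EMGChannelParams(
            base_amplitude=target * (1 - ramp),
            end_amplitude=target * (1 + ramp),
            noise_sd=noise_ratio * target,
            artifact_amplitude=artifact_ratio * target,
        )
        g = pipeline_gain(shape, n_target, config.emg_sampling_rate, wavelet)
        emg_params[ch] = replace(
            shape,
            base_amplitude=shape.base_amplitude / g,
            end_amplitude=shape.end_amplitude / g,
            noise_sd=shape.noise_sd / g,
            artifact_amplitude=shape.artifact_amplitude / g,
        )

    st_trend = cal.phase_trend_shifted("ST", float(cal.ST_CHANGE.loc[lt, slope]))
    sa_trend = cal.phase_trend_shifted("SA", float(cal.SA_CHANGE.loc[lt, slope]))
    pupil_trend = cal.pupil_trend_scaled(cal.pupil_target(lt, slope))
    gaze_params = GazeParams(
        fixation_rate_by_phase=tuple(150.0 * (1 + st_trend / 100.0)),
        saccade_amp_mean_by_phase=tuple(5.0 * (1 + sa_trend / 100.0)),
        pupil_drift_by_phase=tuple(pupil_trend / 100.0),
    )

    growth = float(cal.VAS_GROWTH[lt])
    vas_cells = cal.VAS_CELLS[slope]
    rating_params = RatingParams(
        overall_marks=cal.overall_marks(lt, slope),
        vas_start_by_site={
            site: max(0.0, float(vas_cells.loc[site, lt]) - 2.0 * growth)
            for site in VAS_SITES
        },
        vas_growth_by_site={site: growth for site in VAS_SITES},
    )
    return TrialCalibration(emg=emg_params, gaze=gaze_params, ratings=rating_params)


def generate_trial(
    condition: TrialCondition,
    seed: int,
    duration: float = 1200.0,
    config: RunConfig | None = None,
    calibration: TrialCalibration | None = None,
    participant_id: str = "S01",
) -> TrialRecord:
    """A complete synthetic trial for one design cell.

    EMG and gaze streams span [-60 s, duration + 60 s] (baseline segments
    included); ratings sit on the 5-min grid scaled to ``duration``.
    """
    config = config or RunConfig()
    if calibration is None:
        calibration = study_calibration(condition, duration, config)
    missing = set(CHANNEL_LABELS) - set(calibration.emg)
    if missing:
        raise ValueError(f"uncalibrated condition: missing channels {sorted(missing)}")

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(CHANNEL_LABELS) + 2)
    total = duration + 2 * config.baseline_window
    emg = {
        ch: generate_emg(
            calibration.emg[ch], total, config.emg_sampling_rate,
            np.random.default_rng(child[i]), channel_label=ch,
        )
        for i, ch in enumerate(CHANNEL_LABELS)
    }
    gaze, events = generate_gaze(
        calibration.gaze, duration, config.gaze_sampling_rate,
        np.random.default_rng(child[-2]), config.baseline_window,
    )
    n_marks = int(round(duration / config.rating_interval)) + 1
    times_min = tuple(np.linspace(0, duration / 60.0, n_marks))
    ratings = generate_ratings(
        calibration.ratings, np.random.default_rng(child[-1]), times_min
    )
    return TrialRecord(
        condition=condition,
        participant_id=participant_id,
        emg=emg,
        gaze=gaze,
        ratings=ratings,
        duration=duration,
        ground_truth_saccades=events,
    )
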