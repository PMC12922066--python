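"""Trial containers and delimited-text readers/writers.

A trial directory holds three CSV files (comma-separated, header row, "."
decimal, UTF-8) plus a YAML manifest:

* ``emg.csv`` — time_s and six uV columns M1..M6 (1000 Hz).  Time zero is
  walk onset; the 60 s pre/post baseline segments live at negative times
  and beyond the walking duration.
* ``gaze.csv`` — time_s, azimuth_deg, elevation_deg, pupil_mm, validity
  (100 Hz; validity 0 = valid, >0 = tracker loss).  Gaze angles are
  horizontal/vertical degrees relative to straight ahead in the tracker
  glasses frame.
* ``ratings.csv`` — time_min, vas_shoulder, vas_back, vas_waist, overall.

Numeric round-trips preserve at least 6 significant digits; readers reject
streams whose implied sampling rate deviates more than 1% from the declared
rate, incomplete channel sets, non-monotone timestamps and unknown
condition codes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emg import CHANNEL_LABELS, EMGSignal
from .eye import GazeStream, SaccadeEvent
from .ratings import VAS_SITES, RatingSeries

_FLOAT_FORMAT = "%.10g"


class LoadingType(enum.Enum):
    """A = single-sided, B = cross-body, C = high-position bilateral,
    D = low-position bilateral shoulder carriage."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"


class Slope(enum.Enum):
    FLAT = "flat"
    DOWNHILL = "downhill"
    UPHILL = "uphill"


@dataclass(frozen=True)
class TrialCondition:
    loading_type: LoadingType
    slope: Slope
    load_mass: float = 10.0
    incline_deg: float | None = None

    def __post_init__(self) -> None:
        if self.load_mass <= 0:
            raise ValueError("load_mass must be positive")
        expected = 0.0 if self.slope is Slope.FLAT else 10.0
        if self.incline_deg is None:
            object.__setattr__(self, "incline_deg", expected)
        elif self.incline_deg != expected:
            raise ValueError(
                f"incline_deg must be {expected} for slope {self.slope.value}"
            )

    @classmethod
    def parse(cls, text: str, load_mass: float = 10.0) -> "TrialCondition":
        """Parse a 'A:flat'-style condition code."""
        try:
            lt, slope = text.split(":")
            return cls(LoadingType(lt.strip().upper()), Slope(slope.strip().lower()),
                       load_mass=load_mass)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"invalid condition: {text!r}") from exc

    @property
    def key(self) -> str:
        return f"{self.loading_type.value}:{self.slope.value}"


@dataclass
class TrialRecord:
    """One load-bearing walking trial with all recorded streams.

    EMG and gaze streams cover the walking bout plus 60 s pre/post baseline
    segments; EMG sample zero sits at -baseline_window relative to walk
    onset (t = 0)."""

    condition: TrialCondition
    participant_id: str
    emg: dict[str, EMGSignal]
    gaze: GazeStream
    ratings: RatingSeries
    duration: float = 1200.0
    baseline_window: float = 60.0
    ground_truth_saccades: list[SaccadeEvent] | None = None

    def __post_init__(self) -> None:
        missing = set(CHANNEL_LABELS) - set(self.emg)
        if missing:
            raise ValueError(f"incomplete EMG set: missing {sorted(missing)}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        rates = {s.rate for s in self.emg.values()}
        if len(rates) != 1:
            raise ValueError("EMG channels must share one sampling rate")

    @property
    def emg_rate(self) -> float:
        return next(iter(self.emg.values())).rate

    def emg_times(self) -> np.ndarray:
        n = next(iter(self.emg.values())).n_samples
        return -self.baseline_window + np.arange(n) / self.emg_rate

    def walking_emg(self, channel: str) -> EMGSignal:
        """The walking-bout segment [0, duration) of one EMG channel."""
        s = self.emg[channel]
        i0 = int(round(self.baseline_window * s.rate))
        i1 = i0 + int(round(self.duration * s.rate))
        return EMGSignal(s.samples[i0:i1], s.rate, s.channel_label)

    @property
    def rating_times_s(self) -> list[float]:
        return [t * 60.0 for t in self.ratings.times]


def write_trial(trial: TrialRecord, out_dir: str | Path) -> Path:
    """Write a trial directory (CSV streams + YAML manifest); returns the
    manifest path.  Output is deterministic: the same record writes
    byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    emg_df = pd.DataFrame({"time_s": trial.emg_times()})
    for ch in CHANNEL_LABELS:
        emg_df[ch] = trial.emg[ch].samples
    emg_df.to_csv(out / "emg.csv", index=False, float_format=_FLOAT_FORMAT)

    gaze_df = pd.DataFrame(
        {
            "time_s": trial.gaze.timestamps,
            "azimuth_deg": trial.gaze.azimuth,
            "elevation_deg": trial.gaze.elevation,
            "pupil_mm": trial.gaze.pupil,
            "validity": trial.gaze.validity,
        }
    )
    gaze_df.to_csv(out / "gaze.csv", index=False, float_format=_FLOAT_FORMAT)

    ratings_df = pd.DataFrame(
        {
            "time_min": trial.ratings.times,
            **{f"vas_{s}": trial.ratings.vas[s] for s in VAS_SITES},
            "overall": trial.ratings.overall,
        }
    )
    ratings_df.to_csv(out / "ratings.csv", index=False, float_format=_FLOAT_FORMAT)

    manifest = {
        "participant_id": trial.participant_id,
        "condition": {
            "loading_type": trial.condition.loading_type.value,
            "slope": trial.condition.slope.value,
            "load_mass": trial.condition.load_mass,
            "incline_deg": trial.condition.incline_deg,
        },
        "duration_s": float(trial.duration),
        "baseline_window_s": float(trial.baseline_window),
        "emg_sampling_rate": float(trial.emg_rate),
        "gaze_sampling_rate": float(trial.gaze.rate),
        "files": {"emg": "emg.csv", "gaze": "gaze.csv", "ratings": "ratings.csv"},
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8")
    return manifest_path


def _check_rate(times: np.ndarray, declared: float, what: str) -> None:
    if times.size < 2:
        raise ValueError(f"{what}: stream too short")
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"unordered stream: {what}")
    implied = (times.size - 1) / (times[-1] - times[0])
    if abs(implied - declared) > 0.01 * declared:
        raise ValueError(
            f"{what}: implied rate {implied:.3f} Hz deviates >1% from "
            f"declared {declared:.3f} Hz"
        )


def read_trial(manifest_path: str | Path) -> TrialRecord:
    """Read and validate a trial directory from its manifest."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text(encoding="utf-8"))
    root = manifest_path.parent

    cond = manifest["condition"]
    try:
        condition = TrialCondition(
            loading_type=LoadingType(cond["loading_type"]),
            slope=Slope(cond["slope"]),
            load_mass=float(cond.get("load_mass", 10.0)),
            incline_deg=cond.get("incline_deg"),
        )
    except (ValueError, KeyError) as exc:
        raise ValueError(f"invalid condition: {cond!r}") from exc

    emg_rate = float(manifest["emg_sampling_rate"])
    gaze_rate = float(manifest["gaze_sampling_rate"])
    duration = float(manifest["duration_s"])
    baseline = float(manifest.get("baseline_window_s", 60.0))

    emg_df = pd.read_csv(root / manifest["files"]["emg"])
    missing = set(CHANNEL_LABELS) - set(emg_df.columns)
    if missing:
        raise ValueError(f"incomplete EMG set: missing {sorted(missing)}")
    _check_rate(emg_df["time_s"].to_numpy(), emg_rate, "EMG")
    emg = {
        ch: EMGSignal(emg_df[ch].to_numpy(), emg_rate, ch) for ch in CHANNEL_LABELS
    }

    gaze_df = pd.read_csv(root / manifest["files"]["gaze"])
    _check_rate(gaze_df["time_s"].to_numpy(), gaze_rate, "gaze")
    gaze = GazeStream(
        timestamps=gaze_df["time_s"].to_numpy(),
        azimuth=gaze_df["azimuth_deg"].to_numpy(),
        elevation=gaze_df["elevation_deg"].to_numpy(),
        pupil=gaze_df["pupil_mm"].to_numpy(),
        validity=gaze_df["validity"].to_numpy(),
        rate=gaze_rate,
    )

    ratings_df = pd.read_csv(root / manifest["files"]["ratings"])
    ratings = RatingSeries(
        times=ratings_df["time_min"].to_numpy(),
        vas={s: ratings_df[f"vas_{s}"].to_numpy() for s in VAS_SITES},
        overall=ratings_df["overall"].to_numpy(),
    )

    return TrialRecord(
        condition=condition,
        participant_id=str(manifest["participant_id"]),
        emg=emg,
        gaze=gaze,
        ratings=ratings,
        duration=duration,
        baseline_window=baseline,
    )
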