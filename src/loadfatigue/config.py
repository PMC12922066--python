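"""Run configuration shared across the pipeline stages.

The defaults encode the study conditions: 1000 Hz surface-EMG sampling,
100 Hz wearable gaze tracking, 60 s iEMG windows, 60 s pre/post baseline
segments, self-ratings every 5 min with a ±60 s exclusion zone around each,
db2 wavelet decomposed to level 4, and a 30 °/s I-VT saccade threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class RunConfig:
    emg_sampling_rate: float = 1000.0   # Hz
    gaze_sampling_rate: float = 100.0   # Hz
    iemg_window: float = 60.0           # s
    baseline_window: float = 60.0       # s
    rating_interval: float = 300.0      # s
    exclusion_halfwidth: float = 60.0   # s around each self-rating
    wavelet_name: str = "db2"
    decomposition_level: int = 4
    saccade_velocity_threshold: float = 30.0  # deg/s
    saccade_min_duration: float = 0.01        # s
    significance_alpha: float = 0.05
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "emg_sampling_rate",
            "gaze_sampling_rate",
            "iemg_window",
            "baseline_window",
            "rating_interval",
            "exclusion_halfwidth",
            "saccade_velocity_threshold",
            "saccade_min_duration",
            "significance_alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        if not 0 < self.significance_alpha < 1:
            raise ValueError("significance_alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
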