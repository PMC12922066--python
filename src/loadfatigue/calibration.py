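"""Study calibration tables: condition-level target values for the
4 loading-type x 3 road-slope load-carriage design.

These are the condition means the synthetic-trial generator is calibrated
to reproduce, and the cells the descriptive-summary operations are exercised
on.  Loading types: A = single-sided, B = cross-body, C = high-position
bilateral shoulder, D = low-position bilateral shoulder (10 kg load).
Slopes: flat, downhill, uphill (10 deg incline).  EMG channels M1/M3/M5 are
the left upper-trapezius / lower-trapezius / lumbar sites and M2/M4/M6 the
right-side counterparts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LOADING_TYPES = ("A", "B", "C", "D")
SLOPES = ("flat", "downhill", "uphill")

#: Trial-mean iEMG (uVs) per channel and loading type.
IEMG_BY_TYPE = pd.DataFrame(
    {
        "A": [2.11, 1.16, 0.53, 0.55, 0.57, 1.09],
        "B": [1.88, 1.12, 0.55, 0.53, 1.18, 0.57],
        "C": [1.45, 1.44, 0.71, 0.70, 0.56, 0.56],
        "D": [1.30, 1.30, 0.72, 0.72, 0.60, 0.60],
    },
    index=["M1", "M2", "M3", "M4", "M5", "M6"],
)

#: Trial-mean iEMG (uVs) per channel and road slope.
IEMG_BY_SLOPE = pd.DataFrame(
    {
        "flat": [1.68, 1.27, 0.64, 0.63, 0.71, 0.69],
        "downhill": [1.66, 1.23, 0.57, 0.56, 0.67, 0.78],
        "uphill": [1.70, 1.27, 0.68, 0.68, 0.80, 0.65],
    },
    index=["M1", "M2", "M3", "M4", "M5", "M6"],
)

#: Trial-mean saccade-count change rate (%) per loading type and slope.
ST_CHANGE = pd.DataFrame(
    {
        "flat": [0.41, -2.46, -1.26, -1.31],
        "downhill": [-0.20, -2.71, -2.73, -2.35],
        "uphill": [-4.44, -4.45, -3.79, -4.18],
    },
    index=list(LOADING_TYPES),
)

#: Trial-mean saccade-speed change rate (%).
SS_CHANGE = pd.DataFrame(
    {
        "flat": [-8.10, -6.71, -7.18, -7.12],
        "downhill": [-7.35, -9.08, -8.24, -7.85],
        "uphill": [-9.13, -9.63, -10.29, -8.90],
    },
    index=list(LOADING_TYPES),
)

#: Trial-mean saccade-amplitude change rate (%).
SA_CHANGE = pd.DataFrame(
    {
        "flat": [-8.38, -7.35, -6.88, -6.66],
        "downhill": [-7.79, -6.85, -7.74, -7.65],
        "uphill": [-9.08, -9.55, -7.99, -8.55],
    },
    index=list(LOADING_TYPES),
)

#: Mean pupil-diameter increase (%) per loading type and per slope.
PUPIL_CHANGE_BY_TYPE = pd.Series(
    [5.75, 4.55, 6.92, 6.45], index=list(LOADING_TYPES)
)
PUPIL_CHANGE_BY_SLOPE = pd.Series(
    [4.27, 6.89, 6.59], index=list(SLOPES)
)

#: VAS condition means (cm) per slope, site and loading type.
VAS_CELLS = {
    "flat": pd.DataFrame(
        {
            "A": [5.87, 2.57, 2.10],
            "B": [4.92, 2.32, 2.19],
            "C": [3.19, 2.65, 2.86],
            "D": [4.08, 3.57, 2.60],
        },
        index=["shoulder", "back", "waist"],
    ),
    "downhill": pd.DataFrame(
        {
            "A": [6.04, 3.32, 2.81],
            "B": [4.68, 2.18, 2.50],
            "C": [4.53, 3.08, 2.76],
            "D": [4.19, 2.55, 2.79],
        },
        index=["shoulder", "back", "waist"],
    ),
    "uphill": pd.DataFrame(
        {
            "A": [6.75, 4.33, 4.66],
            "B": [5.25, 3.01, 3.52],
            "C": [5.25, 3.87, 3.27],
            "D": [3.96, 3.13, 3.66],
        },
        index=["shoulder", "back", "waist"],
    ),
}

#: VAS per loading type averaged over slopes (cm), by site.
VAS_BY_TYPE = pd.DataFrame(
    {
        "A": [6.23, 3.41, 3.19],
        "B": [4.95, 2.50, 2.74],
        "C": [4.10, 3.20, 2.96],
        "D": [4.08, 3.08, 3.02],
    },
    index=["shoulder", "back", "waist"],
)

#: Mean VAS growth rate (cm per 5-min interval) per loading type.
VAS_GROWTH = pd.Series([0.502, 0.593, 0.757, 0.666], index=list(LOADING_TYPES))

#: Trial-mean overall-fatigue score per loading type and slope.
OVERALL_FATIGUE = pd.DataFrame(
    {
        "flat": [23.11, 23.70, 22.46, 22.21],
        "downhill": [25.79, 23.05, 22.14, 22.29],
        "uphill": [32.11, 28.00, 27.54, 26.36],
    },
    index=list(LOADING_TYPES),
)

#: Mean eye-metric change rate (%) per fatigue phase (1, 2, 3).
PHASE_TRENDS = pd.DataFrame(
    {
        "ST": [-0.16, -7.33, 5.23],
        "SS": [-0.58, -7.31, -15.96],
        "SA": [-1.32, -7.39, -15.27],
    },
    index=[1, 2, 3],
)

#: Phase durations in minutes for the 20-min trial (0-5, >5-14, >14-20).
PHASE_MINUTES = np.array([5.0, 9.0, 6.0])


def iemg_target(channel: str, loading_type: str, slope: str) -> float:
    """Per-cell iEMG target: loading-type mean modulated by the slope profile.

    The slope table enters as a multiplicative factor normalised by its row
    mean so that averaging the three slope cells recovers the loading-type
    mean.
    """
    type_mean = IEMG_BY_TYPE.loc[channel, loading_type]
    slope_row = IEMG_BY_SLOPE.loc[channel]
    return float(type_mean * slope_row[slope] / slope_row.mean())


def phase_trend_shifted(metric: str, target_trial_mean: float) -> np.ndarray:
    """Phase-trend vector (%) shifted so its time-weighted mean over the
    trial equals the per-condition target; preserves the phase pattern
    (notably the phase-3 saccade-count rebound)."""
    base = PHASE_TRENDS[metric].to_numpy(dtype=float)
    w = PHASE_MINUTES / PHASE_MINUTES.sum()
    return base + (target_trial_mean - float(base @ w))


def pupil_trend_scaled(target_trial_mean: float) -> np.ndarray:
    """Per-phase pupil drift (%) with a rising 0.4/1.0/1.6 shape scaled so
    its time-weighted mean equals the condition target."""
    shape = np.array([0.4, 1.0, 1.6])
    w = PHASE_MINUTES / PHASE_MINUTES.sum()
    return shape * (target_trial_mean / float(shape @ w))


def pupil_target(loading_type: str, slope: str) -> float:
    """Condition pupil-increase target (%): mean of the two marginals."""
    return float(
        (PUPIL_CHANGE_BY_TYPE[loading_type] + PUPIL_CHANGE_BY_SLOPE[slope]) / 2.0
    )


#: Default overall-fatigue trajectory at the 5-min marks (grand average);
#: crosses score 20 between 5 and 10 min and score 30 between 10 and 15 min.
DEFAULT_OVERALL_MARKS = np.array([16.0, 19.0, 25.0, 31.0, 34.0])


def overall_marks(loading_type: str, slope: str) -> np.ndarray:
    """Overall-fatigue mark trajectory shifted to the condition's trial mean."""
    target = OVERALL_FATIGUE.loc[loading_type, slope]
    return DEFAULT_OVERALL_MARKS + (target - DEFAULT_OVERALL_MARKS.mean())
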