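"""Subjective fatigue ratings: VAS site scores and overall-fatigue scores.

VAS marks are made on a 100 mm line and stored internally in mm (0-100) but
reported in cm (0-10), matching the magnitudes used in the study tables.
Overall fatigue is a questionnaire sum (default instrument: 9 items scored
1-5, span 9-45).  All comparisons against printed study values use a single
2-decimal round-half-away-from-zero convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

VAS_SITES = ("shoulder", "back", "waist")

#: Default overall-fatigue instrument: 9 items, each scored 1-5.
OVERALL_ITEMS = 9
OVERALL_MIN = OVERALL_ITEMS * 1.0
OVERALL_MAX = OVERALL_ITEMS * 5.0


def round2(x: float) -> float:
    """Round to 2 decimals, ties away from zero (the reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class RatingSeries:
    """Self-ratings on the 5-min grid: VAS per site (cm) and overall score."""

    times: np.ndarray                  # minutes, subset of {0, 5, 10, 15, 20}
    vas: dict[str, np.ndarray]         # site -> cm values on the 0-10 scale
    overall: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.overall = np.asarray(self.overall, dtype=float)
        self.vas = {k: np.asarray(v, dtype=float) for k, v in self.vas.items()}
        if set(self.vas) != set(VAS_SITES):
            raise ValueError(f"vas must cover sites {VAS_SITES}")
        n = self.times.size
        if self.overall.size != n or any(v.size != n for v in self.vas.values()):
            raise ValueError("ratings columns must have equal length")
        for site, v in self.vas.items():
            if np.any((v < 0) | (v > 10)):
                raise ValueError(f"VAS ({site}) outside the 0-10 cm scale")
        if np.any((self.overall < OVERALL_MIN) | (self.overall > OVERALL_MAX)):
            raise ValueError("overall score outside the instrument range")


@dataclass
class ConditionSummary:
    cell_means: pd.DataFrame         # loading type x slope
    row_means: pd.Series             # per slope
    col_means: pd.Series             # per loading type
    grand_mean: float
    growth_rate: float | None = None
    cumulative: float | None = None


def condition_means(cells: pd.DataFrame, axis: str) -> pd.Series:
    """Unweighted means of a loading-type x slope cell table along one axis.

    ``cells`` is indexed by loading type (rows) with slopes as columns;
    ``axis="slope"`` averages the loading types within each slope,
    ``axis="loading_type"`` averages the slopes within each loading type.
    Results are rounded to 2 decimals.
    """
    if cells.isna().any().any():
        raise ValueError("incomplete design")
    if axis == "slope":
        means = cells.mean(axis=0)
    elif axis == "loading_type":
        means = cells.mean(axis=1)
    else:
        raise ValueError("axis must be 'slope' or 'loading_type'")
    return means.map(round2)


def summarize_cells(cells: pd.DataFrame) -> ConditionSummary:
    return ConditionSummary(
        cell_means=cells,
        row_means=condition_means(cells, "slope"),
        col_means=condition_means(cells, "loading_type"),
        grand_mean=round2(cells.to_numpy().mean()),
    )


def site_ratio(numerator_mean: float, denominator_mean: float) -> float:
    """Plain quotient of two condition means, 2-decimal rounding."""
    if denominator_mean <= 0:
        raise ValueError("undefined ratio")
    return round2(numerator_mean / denominator_mean)


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Percent decrease of comparison relative to reference, 2 decimals."""
    if reference_mean <= 0:
        raise ValueError("undefined change")
    return round2(100.0 * (reference_mean - comparison_mean) / reference_mean)


def growth_and_cumulative(series: RatingSeries | np.ndarray) -> tuple[float, float]:
    """Growth rate (mean successive 5-min increment) and cumulative score
    (sum of post-onset values) of an overall-fatigue or VAS trajectory."""
    values = series.overall if isinstance(series, RatingSeries) else np.asarray(series, float)
    if values.size < 2:
        raise ValueError("insufficient series")
    growth = float(np.mean(np.diff(values)))
    cumulative = float(np.sum(values[1:]))
    return growth, cumulative
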