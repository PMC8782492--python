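"""Snowmelt spring-pulse detection from daily streamflow.

The onset of the annual snowmelt pulse is found with the cumulative-departure
method: with reference flow ``m`` (the calendar-year annual mean, or the
previous year's mean for the lagged variant), the running sum
``C_i = sum_{k<=i} (Q_k - m)`` decreases while flow sits below the reference
and turns upward once snowmelt arrives, so the pulse day is the day ``C``
attains its minimum. Ties resolve to the earliest day; an alternative
``min_plus_one`` convention (first rising day) is exposed because both appear
in the hydrology literature.

All computations run on calendar years (Jan-Dec), not water years. Short gaps
are linearly interpolated up to a configurable run length (default 7 days);
longer gaps mark the year incomplete and it is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .exceptions import IncompleteYearError, InsufficientDataError, UndefinedStatisticError
from .io_formats import DailySeries

__all__ = [
    "AnnualPulseFeature",
    "fill_gaps",
    "annual_mean_flow",
    "spring_pulse_day",
    "dsm_covariate",
    "annual_pulse_features",
    "lagged_pulse_features",
    "pulse_correlation",
]

DEFAULT_GAP_DAYS = 7


@dataclass(frozen=True)
class AnnualPulseFeature:
    """Per gage-year pulse summary.

    ``reference`` records which annual mean anchored the cumulative departure:
    ``current_year_mean`` or ``previous_year_mean`` (the lagged variant).
    """

    station_id: str
    year: int
    annual_mean_flow: float
    pulse_day: int
    reference: str
    complete: bool = True


def fill_gaps(values: np.ndarray, max_gap_days: int) -> np.ndarray:
    """Linearly interpolate NaN runs no longer than *max_gap_days*.

    Leading/trailing gaps and longer runs raise :class:`IncompleteYearError`.
    """
    arr = np.asarray(values, dtype=float).copy()
    isnan = np.isnan(arr)
    if not isnan.any():
        return arr
    if isnan.all():
        raise IncompleteYearError("all days missing")
    if isnan[0] or isnan[-1]:
        raise IncompleteYearError("year starts or ends with a gap")
    # locate NaN runs
    idx = np.flatnonzero(isnan)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        if run.size > max_gap_days:
            raise IncompleteYearError(
                f"gap of {run.size} days exceeds policy of {max_gap_days}"
            )
    good = np.flatnonzero(~isnan)
    arr[isnan] = np.interp(idx, good, arr[good])
    return arr


def annual_mean_flow(flows, gap_policy: int = DEFAULT_GAP_DAYS) -> float:
    """Calendar-year mean flow after gap filling under *gap_policy*."""
    filled = fill_gaps(np.asarray(flows, dtype=float), gap_policy)
    return float(filled.mean())


def spring_pulse_day(flows, reference_mean: float, convention: str = "min") -> int:
    """Julian day of the cumulative-departure minimum for one year of flow.

    ``convention="min"`` returns the day of the minimum itself (the last
    below-reference day, earliest tie); ``"min_plus_one"`` the following day.
    """
    arr = np.asarray(flows, dtype=float)
    if np.isnan(arr).all():
        raise IncompleteYearError("all days missing")
    if np.isnan(arr).any():
        raise IncompleteYearError("gaps must be filled before pulse detection")
    departure = np.cumsum(arr - reference_mean)
    day = int(np.argmin(departure)) + 1
    if convention == "min_plus_one":
        return min(day + 1, arr.size)
    if convention != "min":
        raise ValueError(f"unknown convention {convention!r}")
    return day


def dsm_covariate(julian: float, pulse_day: float) -> float:
    """Daily covariate: Julian day minus the year's pulse day."""
    return julian - pulse_day


def annual_pulse_features(
    series: DailySeries,
    gap_policy: int = DEFAULT_GAP_DAYS,
    convention: str = "min",
) -> list[AnnualPulseFeature]:
    """Current-year-reference pulse features for every complete year."""
    feats = []
    for year in series.years():
        try:
            flows = fill_gaps(series.year_values(year), gap_policy)
        except IncompleteYearError:
            continue
        mean = float(flows.mean())
        day = spring_pulse_day(flows, mean, convention)
        feats.append(AnnualPulseFeature(series.station_id, year, mean, day,
                                        "current_year_mean"))
    return feats


def lagged_pulse_features(
    series: DailySeries,
    gap_policy: int = DEFAULT_GAP_DAYS,
    convention: str = "min",
) -> list[AnnualPulseFeature]:
    """Pulse features referenced to the *previous* calendar year's mean flow.

    The first year of record (and any year whose predecessor is incomplete)
    yields no feature.
    """
    means: dict[int, float] = {}
    complete: dict[int, np.ndarray] = {}
    for year in series.years():
        try:
            flows = fill_gaps(series.year_values(year), gap_policy)
        except IncompleteYearError:
            continue
        complete[year] = flows
        means[year] = float(flows.mean())
    feats = []
    for year, flows in complete.items():
        if year - 1 not in means:
            continue
        ref = means[year - 1]
        day = spring_pulse_day(flows, ref, convention)
        feats.append(AnnualPulseFeature(series.station_id, year, ref, day,
                                        "previous_year_mean"))
    return feats


def pulse_correlation(
    features_current: list[AnnualPulseFeature],
    features_lagged: list[AnnualPulseFeature],
) -> float:
    """Pearson correlation of paired annual pulse days (current vs lagged)."""
    cur = {f.year: f.pulse_day for f in features_current}
    lag = {f.year: f.pulse_day for f in features_lagged}
    years = sorted(set(cur) & set(lag))
    if len(years) < 3:
        raise InsufficientDataError(f"only {len(years)} paired years (need >= 3)")
    x = np.array([cur[y] for y in years], dtype=float)
    y = np.array([lag[y] for y in years], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("pulse-day series has zero variance")
    return float(pearsonr(x, y).statistic)
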