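"""Group-migration responses and herd summary statistics.

A herd-year's *group initiation day* is the first day of the year on which the
maximum number of collared animals observed migrating simultaneously that year
are all in migration ("migrating on day i" means ``start <= i <= end``,
inclusive). The daily binary response for logistic modeling is a monotone step
over days 1..horizon (default Julian day 150): zeros before the group
initiation day, ones from it onward.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .io_formats import MigrationRecord

__all__ = [
    "HerdYearResponse",
    "DEFAULT_HORIZON",
    "simultaneous_counts",
    "group_initiation_day",
    "binary_response",
    "build_responses",
    "herd_summaries",
    "cross_herd_stats",
    "load_herd_year_table",
    "atlantic_rim_table",
]

DEFAULT_HORIZON = 150
HERDS = ("NAR", "SAR")


@dataclass(frozen=True)
class HerdYearResponse:
    herd: str
    year: int
    n_collared: int
    max_simultaneous: int
    group_initiation_day: int
    earliest_individual_day: int
    daily_response: np.ndarray  # binary, days 1..horizon


def simultaneous_counts(records: list[MigrationRecord], n_days: int = 366) -> np.ndarray:
    """Per-day count of animals in migration (days 1..n_days)."""
    if not records:
        raise InsufficientDataError("no migration records for this herd-year")
    herd_years = {(r.herd, r.year) for r in records}
    if len(herd_years) != 1:
        raise ValueError(f"records span multiple herd-years: {sorted(herd_years)}")
    counts = np.zeros(n_days, dtype=int)
    for r in records:
        counts[r.start_day - 1 : min(r.end_day, n_days)] += 1
    return counts


def group_initiation_day(counts: np.ndarray) -> int:
    """First day the per-day count reaches its maximum."""
    counts = np.asarray(counts)
    if counts.size == 0 or counts.max() <= 0:
        raise InsufficientDataError("empty count series")
    return int(np.argmax(counts == counts.max())) + 1


def binary_response(initiation_day: int, horizon: int = DEFAULT_HORIZON) -> np.ndarray:
    """Step response over days 1..horizon: 0 before initiation, 1 from it on.

    Initiation beyond the horizon yields an all-zero vector with a warning —
    such a herd-year carries no positive days in the modeling window.
    """
    if initiation_day < 1:
        raise ValueError("initiation day must be >= 1")
    resp = np.zeros(horizon, dtype=int)
    if initiation_day > horizon:
        warnings.warn(
            f"initiation day {initiation_day} beyond horizon {horizon}: all-zero response",
            stacklevel=2,
        )
        return resp
    resp[initiation_day - 1 :] = 1
    return resp


def build_responses(
    records: list[MigrationRecord], horizon: int = DEFAULT_HORIZON
) -> list[HerdYearResponse]:
    """Group records by herd-year and build each daily step response."""
    out = []
    keys = sorted({(r.herd, r.year) for r in records})
    for herd, year in keys:
        group = [r for r in records if r.herd == herd and r.year == year]
        counts = simultaneous_counts(group)
        init = group_initiation_day(counts)
        out.append(
            HerdYearResponse(
                herd=herd,
                year=year,
                n_collared=len(group),
                max_simultaneous=int(counts.max()),
                group_initiation_day=init,
                earliest_individual_day=min(r.start_day for r in group),
                daily_response=binary_response(init, horizon),
            )
        )
    return out


def herd_summaries(records: list[MigrationRecord]) -> pd.DataFrame:
    """Per herd-year summary: n, earliest individual start, group start,
    maximum simultaneous count, median displacement."""
    if not records:
        raise InsufficientDataError("no migration records")
    rows = []
    for herd, year in sorted({(r.herd, r.year) for r in records}):
        group = [r for r in records if r.herd == herd and r.year == year]
        counts = simultaneous_counts(group)
        rows.append(
            {
                "herd": herd,
                "year": year,
                "n": len(group),
                "earliest_individual_day": min(r.start_day for r in group),
                "group_initiation_day": group_initiation_day(counts),
                "max_simultaneous": int(counts.max()),
                "median_displacement_km": float(
                    np.median([r.displacement_km for r in group])
                ),
            }
        )
    return pd.DataFrame(rows)


def cross_herd_stats(summary: pd.DataFrame) -> dict:
    """Cross-herd comparisons from a per-herd-year summary table.

    * ``median_initiation_diff_days``: median over shared years of the NAR
      minus SAR group-initiation difference;
    * ``displacement_median_diff_km``: across-year median displacement of the
      SAR herd minus that of the NAR herd;
    plus the latest group initiation day and the earliest individual day per
    herd. Fields needing both herds are NaN when a herd is absent.
    """
    out: dict = {
        "latest_group_initiation_day": int(summary["group_initiation_day"].max()),
        "median_initiation_diff_days": float("nan"),
        "displacement_median_diff_km": float("nan"),
    }
    for herd in HERDS:
        sub = summary[summary["herd"] == herd]
        if not sub.empty:
            out[f"earliest_individual_day_{herd}"] = int(
                sub["earliest_individual_day"].min()
            )
    nar = summary[summary["herd"] == "NAR"].set_index("year")
    sar = summary[summary["herd"] == "SAR"].set_index("year")
    shared = nar.index.intersection(sar.index)
    if len(shared) > 0:
        diffs = (
            nar.loc[shared, "group_initiation_day"]
            - sar.loc[shared, "group_initiation_day"]
        )
        out["median_initiation_diff_days"] = float(diffs.median())
    if not nar.empty and not sar.empty:
        out["displacement_median_diff_km"] = float(
            sar["median_displacement_km"].median()
            - nar["median_displacement_km"].median()
        )
    return out


def load_herd_year_table(path) -> pd.DataFrame:
    """Load a herd-year summary CSV (columns: herd, year, n, individual_start,
    herd_start, max_simultaneous, median_displacement_km; start dates as
    ``month/day`` within the row's year) and convert dates to Julian days."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            year = int(row["year"])
            rows.append(
                {
                    "herd": row["herd"].strip(),
                    "year": year,
                    "n": int(row["n"]),
                    "earliest_individual_day": _month_day_to_julian(
                        row["individual_start"], year
                    ),
                    "group_initiation_day": _month_day_to_julian(row["herd_start"], year),
                    "max_simultaneous": int(row["max_simultaneous"]),
                    "median_displacement_km": float(row["median_displacement_km"]),
                }
            )
    return pd.DataFrame(rows)


def _month_day_to_julian(text: str, year: int) -> int:
    import datetime as dt

    month, day = (int(p) for p in text.strip().split("/"))
    return dt.date(year, month, day).timetuple().tm_yday


def atlantic_rim_table() -> pd.DataFrame:
    """The packaged Atlantic Rim herd-year summary table (2005-2018 study years)."""
    ref = resources.files("springpulse.data") / "atlantic_rim_herd_years.csv"
    with resources.as_file(ref) as path:
        return load_herd_year_table(path)
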