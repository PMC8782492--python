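"""Readers, writers and domain containers for daily hydro-climate series and
migration records.

Two file dialects are supported for daily values: plain ``date,value`` CSV and
the USGS NWIS daily-values RDB export (tab-delimited, ``#`` comment block, a
column-name row followed by a column-format row such as ``5s 15s 20d 14n 10s``).
Migration records arrive as a CSV of per-animal spring-migration intervals.

Dates are kept as calendar dates internally; the Julian day-of-year (Jan 1 = 1,
leap-year aware) is computed on demand because every downstream covariate is
expressed in Julian days. Missing values are retained as explicit gaps and are
never interpolated at read time — gap policy belongs to the consumer.
"""

from __future__ import annotations

import calendar
import csv
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, IntegrityError

__all__ = [
    "DailySeries",
    "MigrationRecord",
    "julian_day",
    "year_length",
    "read_daily_values",
    "write_daily_values",
    "read_migration_table",
    "write_migration_table",
]

#: Value codes NWIS uses for absent or unusable daily values.
_MISSING_CODES = {"", "ice", "eqp", "mnt", "dis", "rat", "zfl", "***", "-999999", "nan", "na"}


def julian_day(date: dt.date) -> int:
    """Day-of-year index of *date*: Jan 1 -> 1; Dec 31 -> 365 or 366 (leap)."""
    return date.timetuple().tm_yday


def year_length(year: int) -> int:
    """366 in leap years, else 365."""
    return 366 if calendar.isleap(year) else 365


@dataclass(frozen=True)
class DailySeries:
    """An ordered daily time series of one variable at one station or region.

    Parameters
    ----------
    station_id:
        Streamgage number or region label.
    variable:
        ``"discharge"`` or ``"temperature"``.
    units:
        Declared units, e.g. ``"m3/s"``, ``"ft3/s"`` or ``"degC"``.
    dates:
        Strictly increasing calendar dates. Days absent from the file are
        simply absent here; NaN marks a day present in the file but flagged
        missing.
    values:
        Float array aligned with ``dates``; NaN = missing.
    """

    station_id: str
    variable: str
    units: str
    dates: tuple = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.variable not in ("discharge", "temperature"):
            raise IntegrityError(f"unknown variable {self.variable!r}")
        if len(self.dates) != len(self.values):
            raise IntegrityError("dates and values differ in length")
        object.__setattr__(self, "dates", tuple(self.dates))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        for a, b in zip(self.dates, self.dates[1:]):
            if b <= a:
                raise IntegrityError(f"dates not strictly increasing at {b}")

    def __len__(self) -> int:
        return len(self.dates)

    def years(self) -> list[int]:
        """Calendar years touched by the record, ascending."""
        return sorted({d.year for d in self.dates})

    def year_values(self, year: int) -> np.ndarray:
        """Values for *year* on a full Jan 1..Dec 31 grid, NaN where absent."""
        n = year_length(year)
        out = np.full(n, np.nan)
        for d, v in zip(self.dates, self.values):
            if d.year == year:
                out[julian_day(d) - 1] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": pd.to_datetime(list(self.dates)), "value": self.values})


@dataclass(frozen=True)
class MigrationRecord:
    """One animal's spring-migration interval in one year.

    ``start_day``/``end_day`` are Julian days within ``year``;
    ``displacement_km`` is the straight-line distance between the migration
    start and end locations.
    """

    animal_id: str
    herd: str
    year: int
    start_day: int
    end_day: int
    displacement_km: float

    def __post_init__(self):
        if self.herd not in ("NAR", "SAR"):
            raise IntegrityError(f"unknown herd {self.herd!r}")
        if not (1 <= self.start_day <= self.end_day <= 366):
            raise IntegrityError(
                f"invalid interval [{self.start_day}, {self.end_day}] for {self.animal_id}"
            )
        if self.displacement_km < 0:
            raise IntegrityError("negative displacement")


def _parse_date(text: str, lineno: int) -> dt.date:
    text = text.strip()
    for fmt in ("%Y-%m-%d", "%Y%m%d", "%m/%d/%Y"):
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise FormatError(f"line {lineno}: unparseable date {text!r}")


def _parse_value(text: str) -> float:
    """Parse an NWIS-style value; qualifier codes appended to the number are
    tolerated by splitting on whitespace. Missing codes become NaN."""
    token = text.strip().split()[0] if text.strip() else ""
    if token.lower() in _MISSING_CODES:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"unparseable value {text!r}") from None


def _check_order(pairs: list[tuple[dt.date, float]]) -> None:
    seen = set()
    prev = None
    for d, _ in pairs:
        if d in seen:
            raise IntegrityError(f"duplicate date {d.isoformat()}")
        if prev is not None and d < prev:
            raise IntegrityError(f"out-of-order date {d.isoformat()}")
        seen.add(d)
        prev = d


def _read_csv_daily(path: str) -> tuple[str, list[tuple[dt.date, float]]]:
    pairs: list[tuple[dt.date, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [(i + 1, row) for i, row in enumerate(reader) if row and row[0].strip()]
    if not rows:
        raise FormatError(f"{path}: empty file")
    start = 0
    first = rows[0][1]
    if first[0].strip().lower() in ("date", "datetime"):
        start = 1
    for lineno, row in rows[start:]:
        if len(row) < 2:
            raise FormatError(f"line {lineno}: expected 'date,value'")
        d = _parse_date(row[0], lineno)
        pairs.append((d, _parse_value(row[1])))
    _check_order(pairs)
    return "", pairs


def _read_rdb_daily(path: str) -> tuple[str, list[tuple[dt.date, float]]]:
    with open(path) as fh:
        lines = fh.readlines()
    data = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(lines)
            if ln.strip() and not ln.startswith("#")]
    if len(data) < 2:
        raise FormatError(f"{path}: no RDB header found")
    header = data[0][1].split("\t")
    formats = data[1][1].split("\t")
    if len(formats) != len(header) or not all(f and f[-1] in "sdn" for f in formats):
        raise FormatError(f"{path}: malformed RDB column-format row")
    cols = {name: i for i, name in enumerate(header)}
    if "datetime" not in cols:
        raise FormatError(f"{path}: RDB file lacks a 'datetime' column")
    # The value column: prefer a discharge statistic column, else the first
    # numeric-format column that is not a qualifier (*_cd) column.
    value_idx = None
    for name, i in cols.items():
        if "00060" in name and not name.endswith("_cd"):
            value_idx = i
            break
    if value_idx is None:
        for i, (name, fmt) in enumerate(zip(header, formats)):
            if fmt.endswith("n") and not name.endswith("_cd"):
                value_idx = i
                break
    if value_idx is None:
        raise FormatError(f"{path}: no numeric value column in RDB header")
    station = ""
    pairs: list[tuple[dt.date, float]] = []
    for lineno, ln in data[2:]:
        parts = ln.split("\t")
        if "site_no" in cols and len(parts) > cols["site_no"]:
            station = parts[cols["site_no"]].strip() or station
        d = _parse_date(parts[cols["datetime"]], lineno)
        raw = parts[value_idx] if len(parts) > value_idx else ""
        pairs.append((d, _parse_value(raw)))
    _check_order(pairs)
    return station, pairs


def read_daily_values(
    path: str,
    dialect: str = "csv",
    *,
    station_id: str | None = None,
    variable: str = "discharge",
    units: str | None = None,
) -> DailySeries:
    """Read a daily-values file into a :class:`DailySeries`.

    ``dialect`` is ``"csv"`` (two columns, ``date,value``) or ``"usgs_rdb"``
    (NWIS daily-values export). Missing-coded values are kept as NaN; duplicate
    or out-of-order dates raise :class:`IntegrityError`.
    """
    if dialect == "csv":
        station, pairs = _read_csv_daily(path)
    elif dialect == "usgs_rdb":
        station, pairs = _read_rdb_daily(path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    if units is None:
        units = "ft3/s" if variable == "discharge" else "degC"
    return DailySeries(
        station_id=station_id or station or path,
        variable=variable,
        units=units,
        dates=tuple(d for d, _ in pairs),
        values=np.array([v for _, v in pairs]),
    )


def write_daily_values(series: DailySeries, path: str) -> None:
    """Write a series as ``date,value`` CSV; NaN becomes an empty field."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["date", "value"])
        for d, v in zip(series.dates, series.values):
            w.writerow([d.isoformat(), "" if np.isnan(v) else repr(float(v))])


def read_migration_table(path: str) -> list[MigrationRecord]:
    """Read per-animal migration intervals from CSV.

    Expected columns: ``herd, year, animal_id, start_date, end_date,
    displacement_km``; calendar dates are converted to Julian days with
    leap-year awareness. ``end_date`` before ``start_date`` raises
    :class:`IntegrityError`.
    """
    records: list[MigrationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        needed = {"herd", "year", "animal_id", "start_date", "end_date", "displacement_km"}
        if reader.fieldnames is None or not needed.issubset(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {sorted(needed)}")
        for lineno, row in enumerate(reader, start=2):
            start = _parse_date(row["start_date"], lineno)
            end = _parse_date(row["end_date"], lineno)
            if end < start:
                raise IntegrityError(
                    f"line {lineno}: migration end {end} precedes start {start}"
                )
            records.append(
                MigrationRecord(
                    animal_id=row["animal_id"].strip(),
                    herd=row["herd"].strip(),
                    year=int(row["year"]),
                    start_day=julian_day(start),
                    end_day=julian_day(end),
                    displacement_km=float(row["displacement_km"]),
                )
            )
    return records


def write_migration_table(records: list[MigrationRecord], path: str) -> None:
    """Inverse of :func:`read_migration_table` (dates emitted as ISO)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["herd", "year", "animal_id", "start_date", "end_date", "displacement_km"])
        for r in records:
            start = dt.date(r.year, 1, 1) + dt.timedelta(days=r.start_day - 1)
            end = dt.date(r.year, 1, 1) + dt.timedelta(days=r.end_day - 1)
            w.writerow([r.herd, r.year, r.animal_id, start.isoformat(), end.isoformat(),
                        r.displacement_km])
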