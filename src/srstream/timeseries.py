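"""Monitoring time-series data model, calendar arithmetic, CSV I/O and annual aggregation.

A monitoring series is a sequence of :class:`SampleRecord` — one stream-water
observation per sampling date, carrying discharge ``Q`` (mm/day, normalised to
catchment area) and dissolved 90Sr concentration ``C`` (Bq/m^3).  Time enters
the models as whole days elapsed since the Chernobyl accident on 1986-04-26
(day 0), so every record also carries ``t_days``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ACCIDENT_DATE",
    "SampleRecord",
    "AnnualMean",
    "LoadReport",
    "days_since_accident",
    "read_timeseries",
    "write_timeseries",
    "annual_means",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

#: Time origin of the whole analysis: the Chernobyl accident, day 0.
ACCIDENT_DATE = dt.date(1986, 4, 26)

#: Exact CSV column names for monitoring series files.
CSV_COLUMNS = ("date", "discharge_mm_day", "sr90_bq_m3")
CSV_ERR_COLUMN = "err_pct"


def days_since_accident(date: dt.date) -> int:
    """Whole days elapsed since 1986-04-26 (Gregorian calendar, leap years included).

    Parameters
    ----------
    date
        Calendar date, must not precede the accident.

    Returns
    -------
    int
        Day count with ``days_since_accident(ACCIDENT_DATE) == 0``.
    """
    if isinstance(date, dt.datetime):
        date = date.date()
    if date < ACCIDENT_DATE:
        raise ValueError(
            f"date {date.isoformat()} precedes the accident ({ACCIDENT_DATE.isoformat()}); "
            "the time axis is undefined before day 0"
        )
    return (date - ACCIDENT_DATE).days


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    """One stream-monitoring observation.

    Attributes
    ----------
    date : datetime.date
        Sampling date (daily resolution; no intra-day time).
    q : float
        Stream discharge per unit catchment area, mm/day. Strictly positive.
    c : float
        Dissolved 90Sr concentration, Bq/m^3 (or a dimensionless ratio after
        decay correction). Strictly positive.
    err_pct : float or None
        Relative measurement error of ``c`` in percent, when reported.
    t_days : int
        Whole days since 1986-04-26; derived from ``date``.
    """

    date: dt.date
    q: float
    c: float
    err_pct: float | None = None
    t_days: int = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_days", days_since_accident(self.date))
        if not np.isfinite(self.q) or self.q <= 0:
            raise ValueError(f"discharge must be finite and > 0, got {self.q!r} on {self.date}")
        if not np.isfinite(self.c) or self.c <= 0:
            raise ValueError(f"concentration must be finite and > 0, got {self.c!r} on {self.date}")
        if self.err_pct is not None and (not np.isfinite(self.err_pct) or self.err_pct < 0):
            raise ValueError(f"err_pct must be nonnegative, got {self.err_pct!r}")


@dataclasses.dataclass(frozen=True)
class AnnualMean:
    """Arithmetic annual mean of concentration with a representative time.

    ``t_repr`` is the mean of the contributing samples' ``t_days`` — the time
    at which the long-term trend model is evaluated against ``mean_c``.
    """

    year: int
    mean_c: float
    t_repr: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("an annual mean needs at least one sample")


@dataclasses.dataclass
class LoadReport:
    """Accounting of a CSV load: what was kept and what was excluded (never silently)."""

    n_read: int = 0
    n_kept: int = 0
    n_excluded: int = 0
    exclusions: list[str] = dataclasses.field(default_factory=list)


def _numeric_column(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    raw = df[col]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column '{col}' at data row {row + 1}"
        )
    return coerced


def read_timeseries(path: str | Path) -> tuple[list[SampleRecord], LoadReport]:
    """Read a monitoring series from CSV.

    The file must have columns ``date`` (ISO 8601), ``discharge_mm_day`` and
    ``sr90_bq_m3``; ``err_pct`` is optional.  Rows with missing or nonpositive
    discharge or concentration are excluded and counted in the returned
    :class:`LoadReport` — they never reach log-space computations.  Records are
    returned sorted by date.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"date": str}, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna().to_numpy())[0])
        raise ValueError(
            f"{path}: malformed date {df['date'].iloc[row]!r} in column 'date' at data row {row + 1}"
        )

    q = _numeric_column(df, "discharge_mm_day", str(path))
    c = _numeric_column(df, "sr90_bq_m3", str(path))
    err = (
        _numeric_column(df, CSV_ERR_COLUMN, str(path))
        if CSV_ERR_COLUMN in df.columns
        else pd.Series([np.nan] * len(df))
    )

    report = LoadReport(n_read=len(df))
    records: list[SampleRecord] = []
    for i in range(len(df)):
        qi, ci = q.iloc[i], c.iloc[i]
        if pd.isna(qi) or qi <= 0 or pd.isna(ci) or ci <= 0:
            report.n_excluded += 1
            report.exclusions.append(
                f"row {i + 1} ({df['date'].iloc[i]}): Q={qi!r}, C={ci!r} — missing or nonpositive"
            )
            continue
        ei = err.iloc[i]
        records.append(
            SampleRecord(
                date=dates.iloc[i].date(),
                q=float(qi),
                c=float(ci),
                err_pct=None if pd.isna(ei) else float(ei),
            )
        )
    records.sort(key=lambda r: r.date)
    report.n_kept = len(records)
    if report.n_excluded:
        logger.warning("%s: excluded %d of %d rows", path, report.n_excluded, report.n_read)
    return records, report


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Tabular view of a record sequence (one row per sample)."""
    recs = list(records)
    return pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in recs],
            "t_days": [r.t_days for r in recs],
            "discharge_mm_day": [r.q for r in recs],
            "sr90_bq_m3": [r.c for r in recs],
            "err_pct": [r.err_pct for r in recs],
        }
    )


def write_timeseries(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical column layout (full float precision)."""
    df = records_to_frame(records)
    if all(r.err_pct is None for r in records):
        df = df.drop(columns=["err_pct"])
    df = df.drop(columns=["t_days"])  # derived; recomputed on read
    df.to_csv(path, index=False, float_format="%.17g")  # %.17g round-trips float64


def annual_means(records: Sequence[SampleRecord]) -> list[AnnualMean]:
    """Arithmetic annual means of concentration, one per calendar year with data.

    Annual averaging smooths the strong within-year (snowmelt) fluctuation
    before fitting the long-term trend. Years with a single sample are kept —
    early monitoring was sparse. ``t_repr`` is the mean sampling time of the
    year, the time at which the trend curve is compared with the mean.
    """
    if not records:
        raise ValueError("cannot aggregate an empty record sequence")
    by_year: dict[int, list[SampleRecord]] = {}
    for r in records:
        by_year.setdefault(r.date.year, []).append(r)
    out = []
    for year in sorted(by_year):
        grp = by_year[year]
        out.append(
            AnnualMean(
                year=year,
                mean_c=float(np.mean([r.c for r in grp])),
                t_repr=float(np.mean([r.t_days for r in grp])),
                n=len(grp),
            )
        )
    return out
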