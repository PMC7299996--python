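"""Empirical power-law concentration-discharge regression by period.

The C-Q relationship ``y = p * Q**q`` is fitted per multi-year period by
ordinary least squares of log y on log Q (raw, unbinned points). Concentrations
may first be decay-corrected — divided by the long-term baseline C_ref(t) — to
remove the secular decline before examining the slope; the declining exponent
survives this correction, which is the signature of a changing concentration-
formation process rather than of radioactive decay. Equal-count log-Q binning
is provided for display parity with the classic 10-class scatter summaries.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cq import CQParams, model_exponent
from .timeseries import SampleRecord
from .trend import TrendParams, c_ref

__all__ = [
    "PowerLawFit",
    "CorrectedSeries",
    "decay_correct",
    "split_periods",
    "fit_power_law",
    "fit_periods",
    "bin_by_discharge",
    "slope_trend",
    "SlopeTrendReport",
]


class CorrectedSeries(list):
    """A record list flagged as decay-corrected; guards against double correction."""

    decay_corrected = True


@dataclasses.dataclass(frozen=True)
class PowerLawFit:
    """OLS log-log fit of y on Q for one period: y = p * Q**q."""

    p: float
    q: float
    period: tuple[int, int] | None
    n: int
    r_squared_loglog: float
    t_harmonic_days: float | None = None  # harmonic-mean sample time, for 1/t comparisons

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a power-law fit needs at least 3 points")
        if not (np.isfinite(self.p) and self.p > 0):
            raise ValueError(f"prefactor must be finite and > 0, got {self.p!r}")


def decay_correct(records: Sequence[SampleRecord], trend: TrendParams) -> CorrectedSeries:
    """Divide each concentration by the baseline C_ref at its sampling time.

    Returns dimensionless ratios (observed / long-term trend). Refuses to
    correct an already-corrected series, and a trend with alpha = beta = 0
    (baseline identically zero) is rejected.
    """
    if getattr(records, "decay_corrected", False):
        raise ValueError("series is already decay-corrected; refusing to correct twice")
    if trend.alpha + trend.beta <= 0:
        raise ValueError("degenerate trend: alpha + beta must be > 0 for decay correction")
    out = CorrectedSeries()
    for r in records:
        ref = c_ref(r.t_days, trend)
        if ref <= 0:
            raise ValueError(f"C_ref is zero at t={r.t_days}; correction undefined")
        out.append(SampleRecord(date=r.date, q=r.q, c=r.c / ref, err_pct=r.err_pct))
    return out


def split_periods(
    records: Sequence[SampleRecord],
    periods: Sequence[tuple[int, int]],
) -> tuple[dict[tuple[int, int], list[SampleRecord]], list[SampleRecord]]:
    """Assign records to calendar-year periods (both endpoint years inclusive).

    Periods must be ordered and non-overlapping. Returns the per-period groups
    plus the unassigned records (counted, never silently dropped): the split is
    a partition of the input.
    """
    periods = [tuple(p) for p in periods]
    for (s1, e1), (s2, e2) in zip(periods, periods[1:]):
        if s1 > e1 or s2 > e2 or e1 >= s2:
            raise ValueError(f"periods must be ordered and non-overlapping: {(s1, e1)} vs {(s2, e2)}")
    if periods and periods[-1][0] > periods[-1][1]:
        raise ValueError(f"invalid period {periods[-1]}")
    groups: dict[tuple[int, int], list[SampleRecord]] = {p: [] for p in periods}
    unassigned: list[SampleRecord] = []
    for r in records:
        for start, end in periods:
            if start <= r.date.year <= end:
                groups[(start, end)].append(r)
                break
        else:
            unassigned.append(r)
    return groups, unassigned


def fit_power_law(
    q: Sequence[float],
    y: Sequence[float],
    period: tuple[int, int] | None = None,
    t_days: Sequence[float] | None = None,
) -> PowerLawFit:
    """OLS of log y on log Q: exponent q = slope, prefactor p = exp(intercept)."""
    q = np.asarray(q, dtype=float)
    y = np.asarray(y, dtype=float)
    if q.size < 3:
        raise ValueError(f"need at least 3 pairs, got {q.size}")
    if np.any(q <= 0) or np.any(y <= 0):
        raise ValueError("all discharges and concentrations must be > 0 for a log-log fit")
    if np.all(q == q[0]):
        raise ValueError("zero variance in discharge; the slope is undefined")
    res = stats.linregress(np.log(q), np.log(y))
    t_h = None
    if t_days is not None:
        t_days = np.asarray(t_days, dtype=float)
        t_h = float(stats.hmean(t_days))
    return PowerLawFit(
        p=float(np.exp(res.intercept)),
        q=float(res.slope),
        period=period,
        n=int(q.size),
        r_squared_loglog=float(res.rvalue**2),
        t_harmonic_days=t_h,
    )


def fit_periods(
    records: Sequence[SampleRecord],
    periods: Sequence[tuple[int, int]],
) -> list[PowerLawFit]:
    """One power-law fit per period, carrying the harmonic-mean sample time.

    The harmonic mean is the natural effective time for comparing a period's
    fitted exponent with the model slope d/(b*t), which is proportional to 1/t.
    """
    groups, _ = split_periods(records, periods)
    fits = []
    for period, grp in groups.items():
        if len(grp) < 3:
            raise ValueError(f"period {period} has only {len(grp)} records; need >= 3")
        fits.append(
            fit_power_law(
                [r.q for r in grp],
                [r.c for r in grp],
                period=period,
                t_days=[r.t_days for r in grp],
            )
        )
    return fits


def bin_by_discharge(q: Sequence[float], y: Sequence[float], n_bins: int = 10) -> pd.DataFrame:
    """Equal-count binning in log Q for display: per-bin means and y quartiles.

    Bin counts differ by at most one; equal-count classes avoid empty bins at
    the sparse high-discharge tail. Returns a DataFrame with one row per bin.
    """
    q = np.asarray(q, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(q <= 0) or np.any(y <= 0):
        raise ValueError("all pairs must be positive")
    if q.size < n_bins:
        raise ValueError(f"need at least {n_bins} pairs for {n_bins} bins, got {q.size}")
    order = np.argsort(np.log(q), kind="stable")
    rows = []
    for idx in np.array_split(order, n_bins):
        rows.append(
            {
                "n": idx.size,
                "mean_q": float(np.mean(q[idx])),
                "mean_y": float(np.mean(y[idx])),
                "y_q25": float(np.quantile(y[idx], 0.25)),
                "y_q75": float(np.quantile(y[idx], 0.75)),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class SlopeTrendReport:
    """Period exponents in time order, with the model-slope comparison when available."""

    periods: list[tuple[int, int]]
    midpoint_t_days: list[float]
    exponents: list[float]
    strictly_decreasing: bool
    model_exponents: list[float] | None = None
    rel_deviation: list[float] | None = None


def slope_trend(fits: Sequence[PowerLawFit], cq: CQParams | None = None) -> SlopeTrendReport:
    """Order period fits in time and report whether the exponent declines.

    When model parameters are given, each fitted exponent is compared against
    ``d/(b*t)`` evaluated at the period's harmonic-mean time (exact only at a
    single instant; an effective-time approximation over a period).
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 period fits")
    if any(f.period is None for f in fits):
        raise ValueError("every fit must carry its period")
    fits = sorted(fits, key=lambda f: f.period)
    for f1, f2 in zip(fits, fits[1:]):
        if f1.period[1] >= f2.period[0]:
            raise ValueError(f"periods must be disjoint and ordered: {f1.period} vs {f2.period}")
    midpoints = [
        float(
            (dt.date(p[0], 1, 1) - dt.date(1986, 4, 26)).days
            + ((dt.date(p[1], 12, 31) - dt.date(p[0], 1, 1)).days / 2.0)
        )
        for p in (f.period for f in fits)
    ]
    exps = [f.q for f in fits]
    decreasing = all(e1 > e2 for e1, e2 in zip(exps, exps[1:]))
    model_exps = rel_dev = None
    if cq is not None:
        times = [f.t_harmonic_days if f.t_harmonic_days is not None else m for f, m in zip(fits, midpoints)]
        model_exps = [float(model_exponent(t, cq)) for t in times]
        rel_dev = [abs(e - m) / m for e, m in zip(exps, model_exps)]
    return SlopeTrendReport(
        periods=[f.period for f in fits],
        midpoint_t_days=midpoints,
        exponents=exps,
        strictly_decreasing=decreasing,
        model_exponents=model_exps,
        rel_deviation=rel_dev,
    )
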