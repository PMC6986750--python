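"""Monthly climate variables: temperature, precipitation and the
thresholded cumulative dry-period index.

A "dry spell" is a maximal run of consecutive non-raining days
(precipitation <= wet_cutoff, default 0 mm).  The monthly dry-period
index at threshold k accumulates, for each calendar month, the days that
belong to spells whose *full* length is at least k days; a spell crossing
a month boundary qualifies by its full length but its days are credited
to the month each day falls in.  At k = 1 the index is simply the count
of dry days in the month.  All monthly variables can be linearly
detrended per month-label across years before use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DrySpell",
    "find_dry_spells",
    "monthly_dry_index",
    "zero_ratio",
    "admissible_threshold",
    "monthly_aggregate",
    "linear_detrend",
    "validate_daily_climate",
]


@dataclass(frozen=True)
class DrySpell:
    start: pd.Timestamp
    length: int

    @property
    def days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.length, freq="D")


def validate_daily_climate(daily: pd.DataFrame) -> pd.DataFrame:
    """Check the daily table is gap-free with non-negative precipitation."""
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    daily = daily.sort_values("date").reset_index(drop=True)
    if daily["date"].duplicated().any():
        dup = daily.loc[daily["date"].duplicated(), "date"].iloc[0]
        raise ValueError(f"duplicate date {dup.date()} in daily climate")
    gaps = daily["date"].diff().dropna()
    if (gaps != pd.Timedelta(days=1)).any():
        where = daily["date"][1:][gaps.to_numpy() != pd.Timedelta(days=1)].iloc[0]
        raise ValueError(f"gap in daily climate before {where.date()}")
    if (daily["precip_mm"] < 0).any():
        raise ValueError("negative precipitation in daily climate")
    return daily


def find_dry_spells(daily: pd.DataFrame, wet_cutoff: float = 0.0) -> list[DrySpell]:
    """Maximal runs of days with precipitation <= wet_cutoff.

    Runs may cross month and year boundaries.
    """
    daily = validate_daily_climate(daily)
    dry = (daily["precip_mm"].to_numpy() <= wet_cutoff).astype(int)
    if dry.size == 0:
        return []
    # run boundaries
    edges = np.diff(np.concatenate([[0], dry, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # exclusive
    dates = daily["date"].to_numpy()
    return [DrySpell(start=pd.Timestamp(dates[s]), length=int(e - s))
            for s, e in zip(starts, ends)]


def _empty_matrix(years: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(0.0, index=pd.Index(sorted(set(years)), name="year"),
                        columns=pd.Index(range(1, 13), name="month"))


def monthly_dry_index(
    spells: list[DrySpell], threshold: int, years: "np.ndarray | list[int]"
) -> pd.DataFrame:
    """Accumulated dry-period days per (year, month) at a given threshold.

    Only spells of full length >= threshold contribute; each contributing
    spell adds, to every month it touches, the number of its days falling
    in that month.  The sum over months of a spell's allocation equals its
    length, so no day is double-counted.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1 day")
    mat = _empty_matrix(np.asarray(list(years)))
    for spell in spells:
        if spell.length < threshold:
            continue
        for day in spell.days:
            if day.year in mat.index:
                mat.loc[day.year, day.month] += 1
    return mat


def zero_ratio(matrix: pd.DataFrame) -> float:
    """Fraction of (year, month) cells equal to zero."""
    vals = matrix.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("empty monthly matrix")
    return float(np.mean(vals == 0))


def admissible_threshold(matrix: pd.DataFrame) -> bool:
    """A threshold is admissible when fewer than half the cells are zero.

    Large thresholds produce mostly-zero monthly indices, which make the
    correlation traits unstable; such thresholds are rejected.
    """
    return zero_ratio(matrix) < 0.5


def monthly_aggregate(daily: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly mean temperature (degC) and monthly precipitation sum (mm)."""
    daily = validate_daily_climate(daily)
    g = daily.groupby([daily["date"].dt.year.rename("year"),
                       daily["date"].dt.month.rename("month")])
    temp = g["tmean_c"].mean().unstack("month")
    prec = g["precip_mm"].sum().unstack("month")
    temp.index.name = prec.index.name = "year"
    return temp, prec


def linear_detrend(matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove a linear year trend from each month-label separately.

    For each column (month), values are OLS-regressed on calendar year and
    replaced by the residuals, which are zero-mean per month.  Detrending
    per month-label preserves seasonality while removing the secular trend,
    and the operation is idempotent.
    """
    if len(matrix.index) < 3:
        raise ValueError("linear detrending needs >= 3 years")
    years = matrix.index.to_numpy(dtype=float)
    out = matrix.copy().astype(float)
    for col in matrix.columns:
        y = matrix[col].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3:
            continue
        slope, intercept = np.polyfit(years[ok], y[ok], 1)
        out[col] = y - (slope * years + intercept)
    return out
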