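"""Weather preprocessing: gap interpolation, lag-window aggregation, centering.

Daily local weather series (minimum temperature, precipitation, maximum wind
speed) are turned into year x lag-window matrices: for study year t the
fortnight windows are consecutive 14-day blocks starting 1 January of t-1
(w = 1) with the final block (w = 42) truncated at 31 July of t.  The month
scheme gives the 19 calendar months January t-1 .. July t (used for the
monthly NAO index).  Seasonality is removed by centering each window on its
across-year mean; the centered anomalies C_tw feed the FLM climate term.

Scalar reference covariates: winter NAO (mean of the monthly index December
t-1 through March t) and mean March precipitation of year t, standardized
across study years before model entry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DailyClimateSeries",
    "ClimateMatrix",
    "interpolate_missing",
    "aggregate_windows",
    "monthly_index_matrix",
    "center_windows",
    "scalar_covariate",
    "N_FORTNIGHTS",
    "N_MONTHS",
]

N_FORTNIGHTS = 42
N_MONTHS = 19


@dataclass
class DailyClimateSeries:
    """A contiguous daily series; gaps live in the values (NaN), never dates."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    variable_name: str = "climate"

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must have equal length")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if np.any(deltas != 1):
                raise ValueError("date axis must be contiguous daily with no gaps")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class ClimateMatrix:
    """Year x lag-window climate values C_tw."""

    years: np.ndarray          # (T,) study-year labels
    values: np.ndarray         # (T, W)
    window_scheme: str         # "fortnight" | "month"
    variable_name: str = "climate"
    centered: bool = False

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.years):
            raise ValueError("one row per study year required")
        if np.isnan(self.values).any():
            raise ValueError("climate matrix must have no missing entries")

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def interpolate_missing(series: DailyClimateSeries) -> DailyClimateSeries:
    """Fill gaps by linear interpolation on the date axis.

    Interior runs of missing days are linearly interpolated between the
    bracketing observations; leading/trailing gaps are extended with the
    nearest observed value.  Non-missing values are untouched.
    """
    if np.isnan(series.values).all():
        raise ValueError("all values missing; series unrecoverable")
    if series.n_missing == 0:
        return replace(series, values=series.values.copy())
    s = pd.Series(series.values, index=series.dates)
    filled = s.interpolate(method="time", limit_direction="both")
    return replace(series, values=filled.to_numpy())


def _span_for(study_years: np.ndarray) -> tuple[pd.Timestamp, pd.Timestamp]:
    first, last = int(study_years.min()), int(study_years.max())
    return pd.Timestamp(first - 1, 1, 1), pd.Timestamp(last, 7, 31)


def aggregate_windows(series: DailyClimateSeries, study_years,
                      scheme: str = "fortnight") -> ClimateMatrix:
    """Aggregate a daily series into per-study-year lag-window means.

    For study year t the covered span runs 1 January of t-1 through 31 July
    of t.  Fortnight windows are fixed 14-day blocks anchored at the span
    start; the 42nd block is truncated at 31 July and averages only its
    available days.  The month scheme averages the 19 calendar months.
    """
    study_years = np.asarray(study_years, dtype=int)
    if scheme not in ("fortnight", "month"):
        raise ValueError("scheme must be 'fortnight' or 'month'")
    if np.isnan(series.values).any():
        raise ValueError("aggregate_windows requires a gap-free series; interpolate first")

    n_w = N_FORTNIGHTS if scheme == "fortnight" else N_MONTHS
    out = np.empty((len(study_years), n_w))
    d0, d1 = series.dates[0], series.dates[-1]
    for i, year in enumerate(study_years):
        start = pd.Timestamp(year - 1, 1, 1)
        end = pd.Timestamp(year, 7, 31)
        if start < d0 or end > d1:
            raise ValueError(f"series does not cover study year {year} "
                             f"(needs {start.date()}..{end.date()})")
        lo = (start - d0).days
        hi = (end - d0).days + 1
        vals = series.values[lo:hi]
        if scheme == "fortnight":
            offsets = np.arange(hi - lo)
            win = np.minimum(offsets // 14, n_w - 1)
        else:
            dates = series.dates[lo:hi]
            win = (dates.year - (year - 1)) * 12 + (dates.month - 1)
            win = np.asarray(win)
        sums = np.bincount(win, weights=vals, minlength=n_w)
        counts = np.bincount(win, minlength=n_w)
        out[i] = sums / counts
    return ClimateMatrix(study_years, out, scheme, series.variable_name, centered=False)


def monthly_index_matrix(index: pd.DataFrame, study_years) -> ClimateMatrix:
    """Lag-window matrix from a monthly index (columns year, month, value).

    Window w = 1..19 is calendar month January t-1 .. July t, the monthly
    analogue of :func:`aggregate_windows` for large-scale indices such as NAO.
    """
    study_years = np.asarray(study_years, dtype=int)
    lookup = {(int(r.year), int(r.month)): float(r.value) for r in index.itertuples()}
    out = np.empty((len(study_years), N_MONTHS))
    for i, year in enumerate(study_years):
        for w in range(N_MONTHS):
            y, m = divmod(w, 12)
            key = (year - 1 + y, m + 1)
            if key not in lookup:
                raise ValueError(f"monthly index missing {key[0]}-{key[1]:02d} "
                                 f"needed for study year {year}")
            out[i, w] = lookup[key]
    return ClimateMatrix(study_years, out, "month", "index", centered=False)


def center_windows(matrix: ClimateMatrix) -> ClimateMatrix:
    """Remove seasonality by subtracting each window's across-year mean."""
    if matrix.centered:
        raise ValueError("matrix already centered; refusing to center twice")
    if len(matrix.years) < 2:
        raise ValueError("centering a single-year matrix is degenerate")
    vals = matrix.values - matrix.values.mean(axis=0, keepdims=True)
    return replace(matrix, values=vals, centered=True)


def scalar_covariate(data, rule: str, study_years, standardize: bool = True) -> np.ndarray:
    """Per-year scalar climate covariate.

    ``rule='winter_nao'``: mean of a monthly index (DataFrame with columns
    year, month, value) over December t-1 .. March t.
    ``rule='march_precip'``: mean of a daily series over March of year t.
    Standardized to mean 0, sd 1 across study years unless disabled.
    """
    study_years = np.asarray(study_years, dtype=int)
    out = np.empty(len(study_years))
    if rule == "winter_nao":
        if not isinstance(data, pd.DataFrame):
            raise TypeError("winter_nao needs a monthly index DataFrame")
        lookup = {(int(r.year), int(r.month)): float(r.value) for r in data.itertuples()}
        for i, year in enumerate(study_years):
            months = [(year - 1, 12), (year, 1), (year, 2), (year, 3)]
            vals = []
            for key in months:
                if key not in lookup:
                    raise ValueError(f"monthly index missing {key[0]}-{key[1]:02d}")
                vals.append(lookup[key])
            out[i] = np.mean(vals)
    elif rule == "march_precip":
        if not isinstance(data, DailyClimateSeries):
            raise TypeError("march_precip needs a DailyClimateSeries")
        if np.isnan(data.values).any():
            raise ValueError("march_precip requires a gap-free series")
        d0 = data.dates[0]
        for i, year in enumerate(study_years):
            start = pd.Timestamp(year, 3, 1)
            end = pd.Timestamp(year, 3, 31)
            if start < d0 or end > data.dates[-1]:
                raise ValueError(f"series does not cover March {year}")
            lo, hi = (start - d0).days, (end - d0).days + 1
            out[i] = data.values[lo:hi].mean()
    else:
        raise ValueError("rule must be 'winter_nao' or 'march_precip'")

    if standardize:
        sd = out.std()
        if sd == 0:
            return np.zeros_like(out)
        out = (out - out.mean()) / sd
    return out
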