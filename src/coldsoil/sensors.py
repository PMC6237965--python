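"""Daily summaries, snow detection, snow seasons and freeze-thaw counts
from hourly logger series.

The snow rule: a day is flagged snow-covered when the daily soil-temperature
range stayed at or below ``range_max`` for ``window_days`` consecutive days
ending on that day and the day's maximum stayed strictly below ``tmax_max``.
Shallow soil under an insulating snowpack sits near 0 degC with an almost
flat diurnal cycle, which is what the rule keys on.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

VARIABLES = ("TS", "TA", "RH")

SEASON_MONTHS = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "fall": (9, 10, 11),
}


class Flag(str, Enum):
    SNOW = "snow"
    NO_SNOW = "no-snow"
    UNKNOWN = "unknown"


@dataclass
class SensorSeries:
    """One logger's hourly series of one variable."""

    plot_id: str
    sensor_id: str
    variable: str
    values: pd.Series  # hourly DatetimeIndex -> float

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"variable must be one of {VARIABLES}, got {self.variable!r}")
        if not isinstance(self.values.index, pd.DatetimeIndex):
            raise TypeError("values must be indexed by a DatetimeIndex")
        if not self.values.index.is_monotonic_increasing or self.values.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        vals = self.values.dropna()
        if self.variable in ("TS", "TA"):
            if ((vals < -60) | (vals > 60)).any():
                raise ValueError("temperature outside [-60, 60] degC")
        elif ((vals < 0) | (vals > 100)).any():
            raise ValueError("RH outside [0, 100] %")


@dataclass(frozen=True)
class SnowSeason:
    """Longest contiguous snow run inside the search window."""

    snow_start: dt.date | None
    snow_end: dt.date | None
    duration: int  # snow days within [start, end] (SCD)

    @property
    def empty(self) -> bool:
        return self.snow_start is None


def daily_summaries(series: SensorSeries, min_hours: int = 18) -> pd.DataFrame:
    """Collapse an hourly series to per-day mean/min/max/range.

    Days with fewer than *min_hours* observations are dropped (they are
    treated as unknown downstream).  Returns a DataFrame indexed by date
    with columns mean, min, max, range, n_hours.
    """
    vals = series.values.dropna()
    if vals.empty:
        raise ValueError(f"empty sensor series {series.plot_id}/{series.sensor_id}")
    grp = vals.groupby(vals.index.date)
    out = pd.DataFrame(
        {
            "mean": grp.mean(),
            "min": grp.min(),
            "max": grp.max(),
            "n_hours": grp.size(),
        }
    )
    out["range"] = out["max"] - out["min"]
    out = out[out["n_hours"] >= min_hours]
    out.index = pd.Index(out.index, name="date")
    return out[["mean", "min", "max", "range", "n_hours"]]


def detect_snow_days(
    daily: pd.DataFrame,
    range_max: float = 1.0,
    tmax_max: float = 2.0,
    window_days: int = 2,
) -> pd.Series:
    """Flag each calendar day snow / no-snow / unknown from daily summaries.

    Day d is snow iff the daily range was <= *range_max* on each of the
    *window_days* days ending at d and d's max was < *tmax_max* (strict).
    Days absent from *daily* are unknown and break the window: a day whose
    look-back window touches an unknown day is conservatively no-snow.

    Returns a Series over the full spanned date range with
    :class:`Flag` values.
    """
    if daily.empty:
        return pd.Series(dtype=object)
    dates = pd.date_range(daily.index.min(), daily.index.max(), freq="D").date
    rng = daily["range"].reindex(dates)
    tmax = daily["max"].reindex(dates)
    known = rng.notna().to_numpy()
    low_range = (rng.to_numpy() <= range_max) & known

    ok = low_range.copy()
    for back in range(1, window_days):
        shifted = np.concatenate([np.zeros(back, dtype=bool), low_range[:-back]])
        ok &= shifted
    ok &= known & (tmax.to_numpy() < tmax_max)

    flags = np.empty(len(dates), dtype=object)
    flags[:] = Flag.NO_SNOW
    flags[ok] = Flag.SNOW
    flags[~known] = Flag.UNKNOWN
    return pd.Series(flags, index=pd.Index(dates, name="date"))


def plot_snow_consensus(sensor_flags: list[pd.Series], quorum: float = 0.5) -> pd.Series:
    """Combine per-sensor flags into a plot flag by quorum vote.

    A day is snow iff the fraction of sensors with a known flag reporting
    snow is >= *quorum*; days where no sensor reports are unknown.
    """
    if not sensor_flags:
        raise ValueError("no sensor flag series given")
    df = pd.concat(sensor_flags, axis=1)
    known = (df != Flag.UNKNOWN) & df.notna()
    n_known = known.sum(axis=1)
    n_snow = ((df == Flag.SNOW) & known).sum(axis=1)
    out = pd.Series(Flag.UNKNOWN, index=df.index, dtype=object)
    has = n_known > 0
    snowy = has & (n_snow / n_known.where(n_known > 0, 1) >= quorum)
    out[has] = Flag.NO_SNOW
    out[snowy] = Flag.SNOW
    out.index.name = "date"
    return out.sort_index()


def snow_runs(flags: pd.Series) -> list[tuple[dt.date, dt.date, int]]:
    """All maximal contiguous snow runs as (start, end, length)."""
    runs = []
    start = prev = None
    n = 0
    for date, f in flags.sort_index().items():
        date = date.date() if hasattr(date, "date") else date
        if f == Flag.SNOW and prev is not None and (date - prev).days == 1:
            prev = date
            n += 1
        elif f == Flag.SNOW:
            if start is not None:
                runs.append((start, prev, n))
            start = prev = date
            n = 1
        else:
            if start is not None:
                runs.append((start, prev, n))
            start = prev = None
            n = 0
    if start is not None:
        runs.append((start, prev, n))
    return runs


def snow_season(
    flags: pd.Series,
    window_start: dt.date,
    window_end: dt.date,
) -> SnowSeason:
    """Extract the snow season inside [window_start, window_end].

    Season = longest contiguous run of snow days in the window (first run
    wins ties); duration counts the snow days it spans.  No snow at all
    yields the empty-season sentinel with duration 0.
    """
    idx = pd.Index([d.date() if hasattr(d, "date") else d for d in flags.index])
    sel = (idx >= window_start) & (idx <= window_end)
    win = pd.Series(flags.to_numpy()[sel], index=idx[sel])
    runs = snow_runs(win)
    if not runs:
        return SnowSeason(None, None, 0)
    best = max(runs, key=lambda r: r[2])
    return SnowSeason(best[0], best[1], best[2])


def count_freeze_thaw_events(
    daily: pd.DataFrame,
    threshold: float = -5.0,
    period: tuple[dt.date, dt.date] | None = None,
) -> int:
    """Number of days with daily mean at or below *threshold* (max 1/day)."""
    means = daily["mean"]
    if period is not None:
        idx = pd.Index([d.date() if hasattr(d, "date") else d for d in means.index])
        means = means[(idx >= period[0]) & (idx <= period[1])]
    return int((means <= threshold).sum())


def _study_year(dates: pd.Series) -> np.ndarray:
    """Study-year label: December belongs to the following (Dec-Nov) year."""
    years = np.array([d.year for d in dates])
    months = np.array([d.month for d in dates])
    return np.where(months == 12, years + 1, years)


def seasonal_statistics(daily: pd.DataFrame, plot_id: str = "", sensor_id: str = "") -> pd.DataFrame:
    """Seasonal mean / avg-min / avg-max via monthly aggregation.

    Daily records are averaged to monthly means of daily mean/min/max; a
    season's value is the unweighted mean of its three monthly values.
    Seasons missing any of their three months are flagged incomplete
    (value still computed from the months present).

    Returns a tidy frame: plot_id, sensor_id, year_label, season,
    statistic (mean|avg_min|avg_max), value, complete.
    """
    dates = pd.Index(daily.index)
    df = daily.copy()
    df["month"] = [d.month for d in dates]
    df["study_year"] = _study_year(pd.Series(dates))
    monthly = df.groupby(["study_year", "month"])[["mean", "min", "max"]].mean()

    rows = []
    for year in monthly.index.get_level_values(0).unique():
        for season, months in SEASON_MONTHS.items():
            have = [m for m in months if (year, m) in monthly.index]
            if not have:
                continue
            sub = monthly.loc[[(year, m) for m in have]]
            for stat, col in (("mean", "mean"), ("avg_min", "min"), ("avg_max", "max")):
                rows.append(
                    {
                        "plot_id": plot_id,
                        "sensor_id": sensor_id,
                        "year_label": int(year),
                        "season": season,
                        "statistic": stat,
                        "value": float(sub[col].mean()),
                        "complete": len(have) == len(months),
                    }
                )
    return pd.DataFrame(rows)
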