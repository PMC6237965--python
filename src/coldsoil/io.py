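"""Tidy CSV interchange for sensor campaigns and anomaly series."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .sensors import SensorSeries
from .synthetic import Campaign

SENSOR_COLUMNS = ["plot_id", "sensor_id", "variable", "timestamp", "value"]


def sensor_frame(series: list[SensorSeries]) -> pd.DataFrame:
    parts = []
    for s in series:
        parts.append(
            pd.DataFrame(
                {
                    "plot_id": s.plot_id,
                    "sensor_id": s.sensor_id,
                    "variable": s.variable,
                    "timestamp": s.values.index.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "value": s.values.to_numpy(),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_sensor_csv(series: list[SensorSeries], path: str | Path) -> None:
    sensor_frame(series).to_csv(path, index=False)


def read_sensor_csv(path: str | Path) -> list[SensorSeries]:
    df = pd.read_csv(path)
    missing = set(SENSOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sensor CSV missing columns {sorted(missing)}")
    out = []
    for (plot, sid, var), grp in df.groupby(["plot_id", "sensor_id", "variable"], sort=True):
        idx = pd.DatetimeIndex(pd.to_datetime(grp["timestamp"], utc=True))
        vals = pd.Series(grp["value"].to_numpy(), index=idx).sort_index()
        out.append(SensorSeries(plot_id=str(plot), sensor_id=str(sid), variable=str(var), values=vals))
    return out


def campaign_series(campaign: Campaign) -> list[SensorSeries]:
    return list(campaign.ts.values()) + list(campaign.ta.values()) + list(campaign.rh.values())


def write_truth_csv(campaign: Campaign, path: str | Path) -> None:
    rows = []
    for (plot, year), tr in campaign.truth.items():
        for date, depth in tr.daily_snow_depth.items():
            rows.append(
                {
                    "plot_id": plot,
                    "year_label": year,
                    "date": date.isoformat(),
                    "snow_depth_cm": depth,
                    "snow_present": bool(depth > 0),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_monthly_csv(path: str | Path) -> pd.DataFrame:
    """Monthly series (year, month, value) as used by the anomaly tools."""
    df = pd.read_csv(path)
    need = {"year", "month", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"monthly CSV must have columns {sorted(need)}")
    return df[["year", "month", "value"]].astype({"year": int, "month": int, "value": float})
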