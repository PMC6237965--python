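"""End-to-end experiment: simulate -> sensors -> proxy -> fuse -> snow map
-> compare, emitting one JSON report plus tidy CSV tables."""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, fusion, proxy, sensors, snowmap, synthetic


@dataclass
class ExperimentConfig:
    campaign: synthetic.CampaignConfig = field(default_factory=synthetic.CampaignConfig)
    scene: synthetic.SceneConfig = field(default_factory=synthetic.SceneConfig)
    anomaly: synthetic.AnomalyConfig = field(default_factory=synthetic.AnomalyConfig)
    min_hours: int = 18
    sensor_quorum: float = 0.5
    pixel_quorum: float = 0.5
    ndsi_thresholds: dict[int, float] = field(default_factory=dict)  # year -> threshold
    default_ndsi_threshold: float = 0.4
    fusion_window_half_width: int = 5  # kept small for the daily fusion loop
    satellite: bool = True
    satellite_span: tuple[tuple[int, int], tuple[int, int]] = ((10, 1), (5, 31))
    plot_buffer_m: float = 15.0


def _snow_window(year: int) -> tuple[dt.date, dt.date]:
    return dt.date(year - 1, 10, 1), dt.date(year, 5, 31)


def _sensor_stage(cfg: ExperimentConfig, campaign: synthetic.Campaign) -> dict:
    """Daily summaries, flags, consensus, seasons, FTEs, seasonal stats."""
    c = cfg.campaign
    plot_flags: dict[tuple[str, int], pd.Series] = {}
    seasons: dict[tuple[str, int], sensors.SnowSeason] = {}
    fte_rows, stat_rows = [], []
    for plot in c.plots:
        per_sensor_daily = {}
        for (p, sid), series in campaign.ts.items():
            if p != plot:
                continue
            daily = sensors.daily_summaries(series, min_hours=cfg.min_hours)
            per_sensor_daily[sid] = daily
            st = sensors.seasonal_statistics(daily, plot_id=plot, sensor_id=sid)
            stat_rows.append(st)
            for year in c.years:
                span = (dt.date(year - 1, 12, 1), dt.date(year, 11, 30))
                fte_rows.append(
                    {
                        "plot_id": plot,
                        "sensor_id": sid,
                        "year_label": year,
                        "fte": sensors.count_freeze_thaw_events(daily, period=span),
                    }
                )
        sensor_flags = [
            sensors.detect_snow_days(d) for d in per_sensor_daily.values()
        ]
        consensus = sensors.plot_snow_consensus(sensor_flags, quorum=cfg.sensor_quorum)
        for year in c.years:
            w0, w1 = _snow_window(year)
            idx = pd.Index([d for d in consensus.index])
            sel = (idx >= w0) & (idx <= w1)
            plot_flags[(plot, year)] = consensus[sel]
            seasons[(plot, year)] = sensors.snow_season(consensus, w0, w1)
    return {
        "plot_flags": plot_flags,
        "seasons": seasons,
        "fte": pd.DataFrame(fte_rows),
        "seasonal_stats": pd.concat(stat_rows, ignore_index=True),
    }


def _satellite_stage(cfg: ExperimentConfig, campaign: synthetic.Campaign) -> dict:
    """Scenes -> fused daily fine scenes -> snow maps -> plot flags/SCD_S."""
    c = cfg.campaign
    scfg = cfg.scene
    centers = synthetic.default_plot_centers(c, scfg)
    forest = synthetic.forest_mask_from_lai(c, scfg, centers)
    params = fusion.FusionParams(window_half_width=cfg.fusion_window_half_width)
    sat_flags: dict[tuple[str, int], pd.Series] = {}
    sat_seasons: dict[tuple[str, int], sensors.SnowSeason] = {}
    for year in c.years:
        (m0, d0), (m1, d1) = cfg.satellite_span
        span0 = dt.date(year - 1, m0, d0)
        span1 = dt.date(year, m1, d1)
        masks = synthetic.truth_pixel_masks(campaign, year, scfg, centers)
        masks = {d: m for d, m in masks.items() if span0 <= d <= span1}
        fine, coarse = synthetic.generate_scene_series(
            scfg, masks, forest, seed=c.seed + year
        )
        fine_by_date = {s.date: s for s in fine}
        threshold = cfg.ndsi_thresholds.get(year, cfg.default_ndsi_threshold)
        day_maps: dict[dt.date, np.ndarray] = {}
        for cs in coarse:
            if cs.date in fine_by_date:
                scene = fine_by_date[cs.date]
            else:
                before = [s for s in fine if s.date < cs.date]
                after = [s for s in fine if s.date > cs.date]
                pairs = []
                for anchor in (before[-1] if before else None, after[0] if after else None):
                    if anchor is None:
                        continue
                    canchor = next(x for x in coarse if x.date == anchor.date)
                    pairs.append(
                        fusion.FusionPair(
                            fine=anchor,
                            coarse=fusion.resample_coarse_to_fine(canchor, scfg.fine_geometry),
                        )
                    )
                if not pairs:
                    continue
                scene = fusion.starfm_predict(
                    pairs, fusion.resample_coarse_to_fine(cs, scfg.fine_geometry), params
                )
            ndsi = snowmap.compute_ndsi(scene)
            ndvi = snowmap.compute_ndvi(scene)
            day_maps[cs.date] = snowmap.classify_snow(ndsi, ndvi, threshold)
        for plot in c.plots:
            geom = snowmap.PlotGeometry(plot, *centers[plot], buffer_m=cfg.plot_buffer_m)
            flags, season = snowmap.plot_snow_from_maps(
                day_maps, geom, scfg.fine_geometry, pixel_quorum=cfg.pixel_quorum,
                window=_snow_window(year),
            )
            sat_flags[(plot, year)] = flags
            sat_seasons[(plot, year)] = season
    return {"sat_flags": sat_flags, "sat_seasons": sat_seasons}


def run_pipeline(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full experiment; returns (and optionally writes) the report."""
    c = cfg.campaign
    try:
        campaign = synthetic.generate_campaign(c)
    except Exception as e:  # pragma: no cover - diagnostics only
        raise RuntimeError(f"simulate stage failed: {e}") from e

    sensor_out = _sensor_stage(cfg, campaign)

    reference, local = synthetic.generate_anomaly_records(cfg.anomaly, seed=c.seed)
    assignment = proxy.classify_proxy_years(local, reference, list(c.years))

    sites = compare.classify_sites_by_lai(c.site_lai, seed=c.seed)

    stats = sensor_out["seasonal_stats"].copy()
    stats["site"] = stats["plot_id"].map(sites.classes)
    contrasts = {}
    for season, stat in (("winter", "mean"), ("winter", "avg_min"),
                         ("winter", "avg_max"), ("spring", "mean")):
        sub = stats[
            (stats["season"] == season)
            & (stats["statistic"] == stat)
            & stats["year_label"].isin(c.years)
            & stats["complete"]
        ]
        if sub["year_label"].nunique() == 2:
            rep = compare.fit_year_site_contrast(
                sub, baseline_year=min(c.years), warm_year=max(c.years)
            )
            contrasts[f"{season}_{stat}"] = rep

    fte = sensor_out["fte"]
    fte_plot = fte.groupby(["plot_id", "year_label"])["fte"].mean().reset_index()
    fte_rows = []
    base_y, warm_y = min(c.years), max(c.years)
    for plot in c.plots:
        b = float(fte_plot.query("plot_id == @plot and year_label == @base_y")["fte"].iloc[0])
        w = float(fte_plot.query("plot_id == @plot and year_label == @warm_y")["fte"].iloc[0])
        fte_rows.append(
            {
                "plot_id": plot,
                "site": sites.classes[plot],
                "fte_baseline": b,
                "fte_warm": w,
                "pct_change": (w - b) / b * 100.0 if b > 0 else None,
            }
        )

    scd_rows = []
    for (plot, year), season in sensor_out["seasons"].items():
        scd_rows.append(
            {
                "plot_id": plot,
                "year_label": year,
                "snow_start": season.snow_start.isoformat() if season.snow_start else None,
                "snow_end": season.snow_end.isoformat() if season.snow_end else None,
                "scd_st": season.duration,
            }
        )
    scd = pd.DataFrame(scd_rows)

    agreement = None
    if cfg.satellite:
        try:
            sat = _satellite_stage(cfg, campaign)
        except Exception as e:
            raise RuntimeError(f"satellite stage failed: {e}") from e
        scd["scd_s"] = [
            sat["sat_seasons"][(r.plot_id, r.year_label)].duration for r in scd.itertuples()
        ]
        mats = {}
        for (plot, year), ref in sensor_out["plot_flags"].items():
            mats[(plot, year)] = compare.snow_agreement(ref, sat["sat_flags"][(plot, year)])
        overall = compare.pooled_agreement(list(mats.values()))
        per_year = {
            y: compare.pooled_agreement([m for (p, yy), m in mats.items() if yy == y])
            for y in c.years
        }
        agreement = {
            "overall_accuracy": overall.overall_accuracy,
            "counts": {"tp": overall.tp, "tn": overall.tn, "fp": overall.fp, "fn": overall.fn},
            "excluded": overall.n_excluded,
            "per_year_accuracy": {int(y): m.overall_accuracy for y, m in per_year.items()},
        }

    report = {
        "seeds": {"campaign": c.seed},
        "site_classes": {"classes": sites.classes, "centers": sites.centers},
        "proxy": {
            "baseline_year": assignment.baseline_year,
            "warm_year": assignment.warm_year,
            "annual_means": {int(k): v for k, v in assignment.annual_means.items()},
            "p_values": {int(k): v for k, v in assignment.p_values.items()},
            "omnibus_p": assignment.omnibus_p,
        },
        "seasonal_contrasts": {
            name: {
                "log_transformed": rep.log_transformed,
                "site_contrasts": rep.site_contrasts.to_dict(orient="records"),
            }
            for name, rep in contrasts.items()
        },
        "scd_table": scd.to_dict(orient="records"),
        "fte_table": fte_rows,
        "fte_by_sensor": fte.to_dict(orient="records"),
        "agreement": agreement,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        scd.to_csv(out / "scd.csv", index=False)
        fte.to_csv(out / "fte.csv", index=False)
        sensor_out["seasonal_stats"].to_csv(out / "seasonal_stats.csv", index=False)
    return report
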