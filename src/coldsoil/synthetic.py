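"""Seeded synthetic sensor campaigns, raster scene series and anomaly records.

The generators produce data with the statistical structure the analysis
assumes — snow-insulated soil with a flat diurnal cycle, a warm year with
elevated winter air temperature, delayed snow onset and a thinner snowpack,
fine/coarse reflectance scenes with snow signatures — together with ground
truth (snow seasons, per-pixel snow masks, injected anomaly spikes) so the
detection pipeline can be tested for recovery.

All randomness flows from ``CampaignConfig.seed`` through
``numpy.random.SeedSequence`` children keyed by (plot, year, stream), so
identical configs give bit-identical output.

A "study year" runs December 1 - November 30 and is labelled by its ending
calendar year; each year's series are generated over the enclosing
October 1 (y-1) .. November 30 (y) span so the full snow season and all
four seasons are covered.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .rasters import NODATA, GridGeometry, RasterScene, block_mean, to_int16
from .sensors import SensorSeries, snow_runs, Flag

# stream codes for per-(plot, year) random substreams
_STREAM = {"TA": 0, "SNOW": 1, "TS": 2, "RH": 3, "SCENE": 4, "ANOM": 5}

# Warm-year air offset taper: full strength in DJF, zero in summer.
_OFFSET_WEIGHT = {12: 1.0, 1: 1.0, 2: 1.0, 3: 0.75, 4: 0.5, 5: 0.25,
                  6: 0.0, 7: 0.0, 8: 0.0, 9: 0.0, 10: 0.25, 11: 0.5}


@dataclass
class CampaignConfig:
    """Parameters of a synthetic sensor campaign."""

    n_plots: int = 5
    sensors_per_plot: int = 9
    site_lai: dict[str, float] | None = None
    years: tuple[int, ...] = (2014, 2016)
    warm_year: int | None = 2016
    winter_ta_offset: float = 8.0
    snow_onset_shift: float = 20.0  # days, warm year
    snow_depth_scale: float = 0.4  # warm-year snowfall multiplier
    noise_sd_ts: float = 0.11  # logger calibration RMSE
    noise_sd_ta: float = 1.0
    seed: int = 0

    # air-temperature model
    ta_annual_mean: float = -1.1
    ta_annual_amplitude: float = 17.0
    ta_diurnal_amplitude: float = 4.0
    ta_ar1_phi: float = 0.8

    # snowpack model (Bernoulli-day / Gamma-amount accumulation, degree-day melt)
    precip_prob: float = 0.15
    precip_shape: float = 2.0
    precip_scale_cm: float = 1.5
    min_snowfall_cm: float = 10.0
    melt_rate_cm_per_degday: float = 2.0
    onset_month: int = 10
    onset_day: int = 15

    # soil-temperature model
    insulation_efold_cm: float = 1.2  # diurnal-amplitude damping depth
    mean_insulation_efold_cm: float = 12.0  # mean-coupling damping depth
    coupling_per_hour: float = 1.0  # bare-soil relaxation rate
    coupling_deep_per_hour: float = 0.97  # floor under deep snow
    ta_slow_alpha: float = 0.002  # multi-day smoothing of the mean drive
    ta_damping_alpha: float = 0.15
    treewell_coeff: float = 0.8  # LAI weighting of effective-depth reduction
    treewell_depth_max_cm: float = 25.0

    # relative-humidity model
    rh_mean: float = 70.0
    rh_sd: float = 8.0
    rh_ar1_phi: float = 0.9
    rh_melt_boost: float = 7.0

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.sensors_per_plot < 1:
            raise ValueError("n_plots and sensors_per_plot must be >= 1")
        if not (0.0 < self.snow_depth_scale <= 1.0):
            raise ValueError("snow_depth_scale must be in (0, 1]")
        if min(self.noise_sd_ts, self.noise_sd_ta) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.site_lai is None:
            defaults = [0.05, 0.05, 0.72, 0.72, 1.36]
            self.site_lai = {
                f"P{i+1}": defaults[i % len(defaults)] for i in range(self.n_plots)
            }
        if len(self.site_lai) != self.n_plots:
            raise ValueError("site_lai must name every plot exactly once")

    @property
    def plots(self) -> list[str]:
        return list(self.site_lai)

    def _check_ids(self, plot: str, year: int) -> None:
        if plot not in self.site_lai:
            raise KeyError(f"unknown plot {plot!r}")
        if year not in self.years:
            raise KeyError(f"unknown year {year}")

    def rng(self, plot: str, year: int, stream: str, extra: int = 0) -> np.random.Generator:
        self._check_ids(plot, year)
        key = [self.seed, self.plots.index(plot), int(year), _STREAM[stream], extra]
        return np.random.default_rng(np.random.SeedSequence(key))

    def year_span(self, year: int) -> tuple[dt.date, dt.date]:
        """Generated span enclosing study year *year* (Oct y-1 .. Nov y)."""
        return dt.date(year - 1, 10, 1), dt.date(year, 11, 30)


@dataclass
class TruthRecord:
    """Generator ground truth for one plot-year."""

    plot_id: str
    year_label: int
    snow_start: dt.date | None
    snow_end: dt.date | None
    daily_snow_depth: pd.Series  # date -> cm
    daily_snow_present: pd.Series  # date -> bool

    def __post_init__(self) -> None:
        if self.snow_start is not None and self.snow_start > self.snow_end:
            raise ValueError("snow_start after snow_end")
        if not (self.daily_snow_present == (self.daily_snow_depth > 0)).all():
            raise ValueError("snow_present must equal depth > 0")

    @property
    def duration(self) -> int:
        if self.snow_start is None:
            return 0
        sel = (self.daily_snow_present.index >= self.snow_start) & (
            self.daily_snow_present.index <= self.snow_end
        )
        return int(self.daily_snow_present[sel].sum())


@dataclass
class Campaign:
    config: CampaignConfig
    ts: dict[tuple[str, str], SensorSeries]  # (plot, sensor) -> hourly T_S
    ta: dict[str, SensorSeries]  # plot -> hourly T_A
    rh: dict[str, SensorSeries]  # plot -> hourly RH
    truth: dict[tuple[str, int], TruthRecord]  # (plot, year)


# ---------------------------------------------------------------------------
# air temperature
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation *sd*."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    z = rng.normal(0.0, innov_sd, size=n)
    z[0] = rng.normal(0.0, sd)
    return scipy.signal.lfilter([1.0], [1.0, -phi], z)


def _hourly_index(start: dt.date, end: dt.date) -> pd.DatetimeIndex:
    return pd.date_range(
        pd.Timestamp(start), pd.Timestamp(end) + pd.Timedelta(hours=23), freq="h", tz="UTC"
    )


def simulate_air_temperature(config: CampaignConfig, plot: str, year: int) -> SensorSeries:
    """Hourly air temperature: annual + diurnal sinusoids + AR(1) noise.

    For the configured warm year, ``winter_ta_offset`` is added with full
    strength December-February, tapering to zero in summer.
    """
    config._check_ids(plot, year)
    idx = _hourly_index(*config.year_span(year))
    doy = idx.dayofyear.to_numpy()
    hour = idx.hour.to_numpy()
    seasonal = config.ta_annual_mean + config.ta_annual_amplitude * np.cos(
        2 * np.pi * (doy - 196) / 365.25
    )
    diurnal = config.ta_diurnal_amplitude * np.cos(2 * np.pi * (hour - 15) / 24)
    vals = seasonal + diurnal
    if config.warm_year is not None and year == config.warm_year:
        weights = np.array([_OFFSET_WEIGHT[m] for m in idx.month])
        vals = vals + config.winter_ta_offset * weights
    rng = config.rng(plot, year, "TA")
    vals = vals + _ar1(rng, len(idx), config.ta_ar1_phi, config.noise_sd_ta)
    return SensorSeries(plot_id=plot, sensor_id=f"{plot}-TA", variable="TA",
                        values=pd.Series(vals, index=idx))


# ---------------------------------------------------------------------------
# snowpack
# ---------------------------------------------------------------------------

def _season_onset(config: CampaignConfig, date: dt.date, year: int) -> dt.date:
    """Accumulation onset of the snow season containing *date*."""
    start_year = date.year if date.month >= 7 else date.year - 1
    onset = dt.date(start_year, config.onset_month, config.onset_day)
    if config.warm_year is not None and year == config.warm_year:
        onset = onset + dt.timedelta(days=round(config.snow_onset_shift))
    return onset


def simulate_snowpack(ta_daily: pd.Series, config: CampaignConfig, year: int,
                      plot: str | None = None) -> pd.Series:
    """Daily snow depth (cm) driven by a daily-mean air-temperature series.

    Snow accumulates on stochastic precipitation days when the daily mean is
    below 0 degC (after the season onset date), and melts at a degree-day
    rate when it is above 0.  The configured warm year delays onset by
    ``snow_onset_shift`` days and scales snowfall by ``snow_depth_scale``.
    """
    dates = pd.Index([d.date() if hasattr(d, "date") else d for d in ta_daily.index])
    gaps = np.diff([d.toordinal() for d in dates])
    if len(gaps) and gaps.max() > 7:
        raise ValueError("air-temperature series has a gap longer than 7 days")
    rng = config.rng(plot or config.plots[0], year, "SNOW")
    n = len(dates)
    precip_day = rng.random(n) < config.precip_prob
    amounts = config.min_snowfall_cm + rng.gamma(
        config.precip_shape, config.precip_scale_cm, size=n
    )
    scale = (
        config.snow_depth_scale
        if (config.warm_year is not None and year == config.warm_year)
        else 1.0
    )
    depth = np.zeros(n)
    d = 0.0
    tvals = ta_daily.to_numpy()
    for i, (date, t) in enumerate(zip(dates, tvals)):
        if t < 0 and precip_day[i] and date >= _season_onset(config, date, year):
            d += amounts[i] * scale
        elif t > 0 and d > 0:
            d = max(0.0, d - config.melt_rate_cm_per_degday * t)
        depth[i] = d
    return pd.Series(depth, index=dates, name="snow_depth_cm")


# ---------------------------------------------------------------------------
# soil temperature
# ---------------------------------------------------------------------------

def _soil_trajectory(ta_vals: np.ndarray, depth_hourly: np.ndarray, lai: float,
                     config: CampaignConfig) -> np.ndarray:
    """Deterministic hourly soil-temperature path (no sensor noise).

    The soil relaxes toward an insulation-weighted blend of damped/lagged
    air temperature and the ~0 degC subnivean floor; diurnal amplitude is
    damped on a shallow e-fold and the multi-day mean on a deeper one.
    Canopy (LAI) reduces the effective insulating depth of a shallow
    snowpack (tree-well effect), so forested soil under thin snow tracks
    cold air more closely.
    """
    if (depth_hourly < 0).any():
        raise ValueError("snow depth must be non-negative")
    eff = depth_hourly / np.where(
        depth_hourly < config.treewell_depth_max_cm,
        1.0 + config.treewell_coeff * lai,
        1.0,
    )
    f = np.exp(-eff / config.insulation_efold_cm)
    f_mean = np.exp(-eff / config.mean_insulation_efold_cm)
    a = config.ta_damping_alpha
    ema = scipy.signal.lfilter([a], [1.0, -(1.0 - a)], ta_vals, zi=[(1 - a) * ta_vals[0]])[0]
    a2 = config.ta_slow_alpha
    ema_slow = scipy.signal.lfilter([a2], [1.0, -(1.0 - a2)], ta_vals, zi=[(1 - a2) * ta_vals[0]])[0]
    # thin snow flattens the diurnal cycle quickly (fast e-fold) but still
    # transmits the multi-day mean drive (slow e-fold): the thin warm-year
    # pack leaves soil colder than a deep baseline pack pinned near 0 degC
    target = f_mean * ema_slow + f * (ema - ema_slow)
    c = np.clip(
        config.coupling_deep_per_hour
        + (config.coupling_per_hour - config.coupling_deep_per_hour) * f,
        0.0,
        1.0,
    )
    ts = np.empty_like(ta_vals)
    t = target[0]
    for i in range(len(ta_vals)):
        t = t + c[i] * (target[i] - t)
        ts[i] = t
    return ts


def simulate_soil_temperature(ta_hourly: SensorSeries, snow_depth: pd.Series,
                              lai: float, config: CampaignConfig,
                              rng: np.random.Generator | None = None,
                              sensor_id: str = "S1") -> SensorSeries:
    """Hourly soil temperature for one sensor (trajectory + sensor noise)."""
    if (snow_depth < 0).any():
        raise ValueError("snow depth must be non-negative")
    idx = ta_hourly.values.index
    day_idx = pd.Index([d.date() for d in idx])
    depth_hourly = snow_depth.reindex(day_idx)
    if depth_hourly.isna().any():
        raise ValueError("snow-depth series does not span the air-temperature dates")
    ts = _soil_trajectory(ta_hourly.values.to_numpy(), depth_hourly.to_numpy(), lai, config)
    if config.noise_sd_ts > 0:
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM["TS"]]))
        ts = ts + rng.normal(0.0, config.noise_sd_ts, size=len(ts))
    return SensorSeries(plot_id=ta_hourly.plot_id, sensor_id=sensor_id, variable="TS",
                        values=pd.Series(ts, index=idx))


def _simulate_rh(config: CampaignConfig, plot: str, year: int,
                 ta_daily: pd.Series, depth: pd.Series) -> SensorSeries:
    idx = _hourly_index(*config.year_span(year))
    rng = config.rng(plot, year, "RH")
    vals = config.rh_mean + _ar1(rng, len(idx), config.rh_ar1_phi, config.rh_sd)
    melt_days = set(depth.index[(depth.to_numpy() > 0) & (ta_daily.reindex(depth.index) > 0)])
    day_idx = pd.Index([d.date() for d in idx])
    vals = vals + config.rh_melt_boost * np.fromiter(
        (d in melt_days for d in day_idx), dtype=float, count=len(idx)
    )
    vals = np.clip(vals, 0.0, 100.0)
    return SensorSeries(plot_id=plot, sensor_id=f"{plot}-RH", variable="RH",
                        values=pd.Series(vals, index=idx))


def truth_from_depth(plot: str, year: int, depth: pd.Series,
                     window: tuple[dt.date, dt.date] | None = None) -> TruthRecord:
    """Truth record from a depth series; season = longest snow run in window."""
    present = depth > 0
    if window is None:
        window = (dt.date(year - 1, 10, 1), dt.date(year, 5, 31))
    arr = np.empty(len(present), dtype=object)
    arr[:] = Flag.NO_SNOW
    arr[present.to_numpy()] = Flag.SNOW
    flags = pd.Series(arr, index=present.index)
    sel = (flags.index >= window[0]) & (flags.index <= window[1])
    runs = snow_runs(flags[sel])
    if runs:
        start, end, _ = max(runs, key=lambda r: r[2])
    else:
        start = end = None
    return TruthRecord(plot_id=plot, year_label=year, snow_start=start, snow_end=end,
                       daily_snow_depth=depth, daily_snow_present=present)


def generate_campaign(config: CampaignConfig) -> Campaign:
    """Full campaign: per-sensor T_S, per-plot T_A / RH, plus truth records."""
    ts: dict[tuple[str, str], SensorSeries] = {}
    ta: dict[str, SensorSeries] = {}
    rh: dict[str, SensorSeries] = {}
    truth: dict[tuple[str, int], TruthRecord] = {}
    for plot in config.plots:
        lai = config.site_lai[plot]
        ta_parts, rh_parts = [], []
        ts_parts: dict[str, list[pd.Series]] = {
            f"{plot}-S{i+1}": [] for i in range(config.sensors_per_plot)
        }
        for year in config.years:
            air = simulate_air_temperature(config, plot, year)
            ta_daily = air.values.groupby([d.date() for d in air.values.index]).mean()
            ta_daily.index = pd.Index(ta_daily.index)
            depth = simulate_snowpack(ta_daily, config, year, plot=plot)
            truth[(plot, year)] = truth_from_depth(plot, year, depth)
            traj = _soil_trajectory(
                air.values.to_numpy(),
                depth.reindex(pd.Index([d.date() for d in air.values.index])).to_numpy(),
                lai,
                config,
            )
            for i, sid in enumerate(ts_parts):
                rng = config.rng(plot, year, "TS", extra=i)
                noise = (
                    rng.normal(0.0, config.noise_sd_ts, size=len(traj))
                    if config.noise_sd_ts > 0
                    else 0.0
                )
                ts_parts[sid].append(pd.Series(traj + noise, index=air.values.index))
            ta_parts.append(air.values)
            rh_parts.append(_simulate_rh(config, plot, year, ta_daily, depth).values)
        ta[plot] = SensorSeries(plot, f"{plot}-TA", "TA", pd.concat(ta_parts))
        rh[plot] = SensorSeries(plot, f"{plot}-RH", "RH", pd.concat(rh_parts))
        for sid, parts in ts_parts.items():
            ts[(plot, sid)] = SensorSeries(plot, sid, "TS", pd.concat(parts))
    return Campaign(config=config, ts=ts, ta=ta, rh=rh, truth=truth)


# ---------------------------------------------------------------------------
# raster scenes
# ---------------------------------------------------------------------------

DEFAULT_SIGNATURES: dict[str, dict[str, int]] = {
    # scaled reflectance x 10^4
    "open": {"green": 1800, "red": 1500, "nir": 3500, "swir2": 3000},
    "forest": {"green": 1600, "red": 900, "nir": 4000, "swir2": 1800},
    "snow": {"green": 7500, "red": 7000, "nir": 6000, "swir2": 800},
}


@dataclass
class SceneConfig:
    """Geometry and radiometry of the synthetic scene series."""

    fine_shape: tuple[int, int] = (60, 60)
    ratio: int = 10  # coarse:fine cell-size ratio (grids nest exactly)
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 1800.0)
    fine_interval: int = 16  # days between fine acquisitions
    cloud_fraction: float = 0.15  # expected masked fraction of fine scenes
    noise_sd: float = 0.0  # scaled-reflectance units
    gradient_amplitude: float = 500.0  # static spatial field, scaled units
    seasonal_amplitude: float = 200.0  # uniform temporal offset, scaled units
    signatures: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SIGNATURES.items()}
    )

    def __post_init__(self) -> None:
        if self.fine_shape[0] % self.ratio or self.fine_shape[1] % self.ratio:
            raise ValueError("fine grid must be divisible by the coarse:fine ratio")

    @property
    def fine_geometry(self) -> GridGeometry:
        return GridGeometry(self.origin[0], self.origin[1], self.cell_size,
                            self.fine_shape[0], self.fine_shape[1])

    @property
    def coarse_geometry(self) -> GridGeometry:
        return GridGeometry(self.origin[0], self.origin[1], self.cell_size * self.ratio,
                            self.fine_shape[0] // self.ratio, self.fine_shape[1] // self.ratio)


def _cloud_mask(rng: np.random.Generator, shape: tuple[int, int], fraction: float) -> np.ndarray:
    """Random rectangular cloud patches with expected coverage *fraction*."""
    bad = np.zeros(shape, dtype=bool)
    if fraction <= 0:
        return bad
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    target = fraction * shape[0] * shape[1]
    while bad.sum() < target:
        h = rng.integers(2, max(3, shape[0] // 4))
        w = rng.integers(2, max(3, shape[1] // 4))
        r = rng.integers(0, shape[0] - h + 1)
        c = rng.integers(0, shape[1] - w + 1)
        bad[r: r + h, c: c + w] = True
    return bad


def generate_scene_series(
    scfg: SceneConfig,
    truth_masks: dict[dt.date, np.ndarray],
    forest_mask: np.ndarray,
    seed: int,
) -> tuple[list[RasterScene], list[RasterScene]]:
    """Fine (sparse) and coarse (daily) scenes over the truth-mask dates.

    Per-pixel reflectance comes from land-class signatures (forest / open)
    overridden by the snow signature where the truth mask is snow, plus a
    static spatial gradient and a spatially uniform seasonal offset.  The
    coarse scene is the block mean of the (noise-free-cast) fine scene;
    fine scenes are emitted every ``fine_interval`` days with random cloud
    patches in their QA band.
    """
    nr, nc = scfg.fine_shape
    if forest_mask.shape != (nr, nc):
        raise ValueError("forest_mask shape mismatch")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM["SCENE"]]))
    rows, cols = np.mgrid[0:nr, 0:nc]
    gradient = scfg.gradient_amplitude * np.sin(2 * np.pi * (rows + cols) / (nr + nc))

    dates = sorted(truth_masks)
    fine_scenes: list[RasterScene] = []
    coarse_scenes: list[RasterScene] = []
    for i, date in enumerate(dates):
        snow = np.asarray(truth_masks[date], dtype=bool)
        if snow.shape != (nr, nc):
            raise ValueError(f"truth mask for {date} has wrong shape")
        doy = date.timetuple().tm_yday
        seasonal = scfg.seasonal_amplitude * np.sin(2 * np.pi * doy / 365.25)
        bands_clean: dict[str, np.ndarray] = {}
        for band in ("green", "red", "nir", "swir2"):
            base = np.where(
                forest_mask,
                scfg.signatures["forest"][band],
                scfg.signatures["open"][band],
            ).astype(float)
            base = np.where(snow, float(scfg.signatures["snow"][band]), base)
            bands_clean[band] = np.clip(base + gradient + seasonal, 0, 1e4)

        emit_fine = i % scfg.fine_interval == 0
        if emit_fine:
            bad = _cloud_mask(rng, (nr, nc), scfg.cloud_fraction)
            fb = {}
            for band, clean in bands_clean.items():
                noisy = clean + (
                    rng.normal(0.0, scfg.noise_sd, clean.shape) if scfg.noise_sd > 0 else 0.0
                )
                fb[band] = to_int16(noisy, invalid=bad)
            fine_scenes.append(
                RasterScene(date=date, tier="fine", geometry=scfg.fine_geometry,
                            bands=fb, qa=~bad)
            )

        # coarse sensor sees block-mean radiance of the stored fine signal
        fine_store = {b: to_int16(v) for b, v in bands_clean.items()}
        cbad = _cloud_mask(rng, scfg.coarse_geometry.shape, scfg.cloud_fraction / 3.0)
        cb = {}
        for band, stored in fine_store.items():
            cmean = block_mean(stored.astype(float), scfg.ratio)
            if scfg.noise_sd > 0:
                cmean = cmean + rng.normal(0.0, scfg.noise_sd / scfg.ratio, cmean.shape)
            cb[band] = to_int16(cmean, invalid=cbad)
        coarse_scenes.append(
            RasterScene(date=date, tier="coarse", geometry=scfg.coarse_geometry,
                        bands=cb, qa=~cbad)
        )
    return fine_scenes, coarse_scenes


def default_plot_centers(config: CampaignConfig, scfg: SceneConfig) -> dict[str, tuple[float, float]]:
    """Spread plot centers along the fine-grid diagonal, on pixel centers."""
    g = scfg.fine_geometry
    xs, ys = g.pixel_centers()
    n = config.n_plots
    out = {}
    for i, plot in enumerate(config.plots):
        r = int((i + 0.5) * g.nrows / n)
        c = int((i + 0.5) * g.ncols / n)
        out[plot] = (float(xs[r, c]), float(ys[r, c]))
    return out


def truth_pixel_masks(
    campaign: Campaign,
    year: int,
    scfg: SceneConfig,
    plot_centers: dict[str, tuple[float, float]],
    plot_radius_m: float = 60.0,
) -> dict[dt.date, np.ndarray]:
    """Per-day fine-grid snow masks from campaign truth.

    Background pixels are snow when a majority of plots have snow that day;
    a disk around each plot center carries that plot's own truth.
    """
    g = scfg.fine_geometry
    xs, ys = g.pixel_centers()
    plots = campaign.config.plots
    truth = {p: campaign.truth[(p, year)].daily_snow_present for p in plots}
    dates = truth[plots[0]].index
    disks = {
        p: (xs - plot_centers[p][0]) ** 2 + (ys - plot_centers[p][1]) ** 2
        <= plot_radius_m**2
        for p in plots
    }
    masks: dict[dt.date, np.ndarray] = {}
    for date in dates:
        flags = {p: bool(truth[p].get(date, False)) for p in plots}
        background = sum(flags.values()) * 2 >= len(plots)
        m = np.full(g.shape, background, dtype=bool)
        for p in plots:
            m[disks[p]] = flags[p]
        masks[date] = m
    return masks


def forest_mask_from_lai(
    config: CampaignConfig,
    scfg: SceneConfig,
    plot_centers: dict[str, tuple[float, float]],
    plot_radius_m: float = 60.0,
    lai_threshold: float = 0.5,
) -> np.ndarray:
    """Forest/open land-class grid: forested disks around high-LAI plots."""
    g = scfg.fine_geometry
    xs, ys = g.pixel_centers()
    mask = np.zeros(g.shape, dtype=bool)
    for p, (x, y) in plot_centers.items():
        if config.site_lai[p] >= lai_threshold:
            mask |= (xs - x) ** 2 + (ys - y) ** 2 <= plot_radius_m**2
    return mask


# ---------------------------------------------------------------------------
# anomaly records
# ---------------------------------------------------------------------------

@dataclass
class AnomalyConfig:
    start_year: int = 1950
    end_year: int = 2017
    baseline: tuple[int, int] = (1961, 1990)
    trend_linear: float = 0.005  # degC / year from baseline start
    trend_quadratic: float = 0.0002  # degC / year^2
    noise_sd: float = 0.5
    warm_year: int | None = 2016  # study-year label (Dec-Nov) given the spike
    spike: float = 2.5  # mean annual anomaly added to the warm study year
    climatology_mean: float = 2.0
    climatology_amplitude: float = 16.0

    def __post_init__(self) -> None:
        if not (self.start_year <= self.baseline[0] <= self.baseline[1] <= self.end_year):
            raise ValueError("baseline window must lie inside the generated span")


# winter-heavy monthly spike profile; mean over a Dec-Nov study year is 1
_SPIKE_PROFILE = {12: 1.5, 1: 1.5, 2: 1.5, 3: 1.0, 4: 1.0, 5: 1.0,
                  6: 0.6, 7: 0.6, 8: 0.6, 9: 0.9, 10: 0.9, 11: 0.9}


def generate_anomaly_records(
    acfg: AnomalyConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference and local monthly anomaly frames (year, month, value).

    Both series share a climatology plus linear-and-quadratic trend; noise
    is independent between them, and the designated warm study year gets an
    added local anomaly spike, largest in winter.
    """
    from .proxy import monthly_anomalies  # local import avoids a cycle

    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM["ANOM"]]))
    years = np.arange(acfg.start_year, acfg.end_year + 1)
    rows = [(y, m) for y in years for m in range(1, 13)]
    yv = np.array([r[0] for r in rows], dtype=float)
    mv = np.array([r[1] for r in rows])
    clim = acfg.climatology_mean + acfg.climatology_amplitude * np.cos(
        2 * np.pi * (mv - 7) / 12
    )
    t = yv - acfg.baseline[0]
    trend = acfg.trend_linear * t + acfg.trend_quadratic * t**2

    def frame(noise: np.ndarray, spike: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": [r[0] for r in rows], "month": mv, "value": clim + trend + noise + spike}
        )

    ref_noise = rng.normal(0.0, acfg.noise_sd, len(rows)) if acfg.noise_sd > 0 else np.zeros(len(rows))
    loc_noise = rng.normal(0.0, acfg.noise_sd, len(rows)) if acfg.noise_sd > 0 else np.zeros(len(rows))

    spike = np.zeros(len(rows))
    if acfg.warm_year is not None and acfg.spike != 0.0:
        study_year = np.where(mv == 12, yv + 1, yv)
        hit = study_year == acfg.warm_year
        spike[hit] = acfg.spike * np.array([_SPIKE_PROFILE[m] for m in mv[hit]])

    reference = monthly_anomalies(frame(ref_noise, np.zeros(len(rows))), acfg.baseline)
    local = monthly_anomalies(frame(loc_noise, spike), acfg.baseline)
    return reference, local
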