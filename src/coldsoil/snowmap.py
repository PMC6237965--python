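"""NDSI/NDVI computation, threshold snow classification, plot extraction.

Classification: a pixel is snow when its NDSI exceeds the period-specific
primary threshold (strict >, up to 1), or — to avoid under-mapping thin or
canopy-obscured snow — when NDSI falls in an intermediate band and NDVI
sits inside a narrow auxiliary window.  Pixels whose green reflectance is
at or below ``green_floor`` are masked before the index is computed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasters import RasterScene
from .sensors import Flag, SnowSeason, snow_season

SNOW, NO_SNOW, MASKED = 1, 0, 255  # uint8 map encoding


@dataclass(frozen=True)
class PlotGeometry:
    plot_id: str
    x: float
    y: float
    buffer_m: float = 15.0


@dataclass
class NdviRule:
    """Auxiliary acceptance window: ndsi_lo < NDSI < ndsi_hi and
    ndvi_lo <= NDVI <= ndvi_hi."""

    ndsi_lo: float = 0.1
    ndsi_hi: float = 0.3
    ndvi_lo: float = 0.08
    ndvi_hi: float = 0.12


@dataclass
class IndexGrid:
    date: dt.date
    index: str  # "NDSI" | "NDVI"
    values: np.ndarray  # float, NaN where masked
    geometry: object


def compute_ndsi(scene: RasterScene, green_floor: float = 0.1) -> IndexGrid:
    """(green - swir2) / (green + swir2); green <= floor masked first."""
    g = scene.reflectance("green")
    s = scene.reflectance("swir2")
    g = np.where(g <= green_floor, np.nan, g)
    denom = g + s
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom != 0, (g - s) / denom, np.nan)
    return IndexGrid(scene.date, "NDSI", vals, scene.geometry)


def compute_ndvi(scene: RasterScene) -> IndexGrid:
    """(nir - red) / (nir + red); nodata propagates."""
    n = scene.reflectance("nir")
    r = scene.reflectance("red")
    denom = n + r
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom != 0, (n - r) / denom, np.nan)
    return IndexGrid(scene.date, "NDVI", vals, scene.geometry)


def classify_snow(
    ndsi: IndexGrid,
    ndvi: IndexGrid,
    primary_threshold: float,
    ndvi_rule: NdviRule | None = None,
) -> np.ndarray:
    """uint8 snow map: 1 snow, 0 no-snow, 255 masked."""
    rule = ndvi_rule or NdviRule()
    if ndsi.values.shape != ndvi.values.shape:
        raise ValueError("index grids must be aligned")
    s, v = ndsi.values, ndvi.values
    primary = (s > primary_threshold) & (s <= 1.0)
    auxiliary = (
        (s > rule.ndsi_lo) & (s < rule.ndsi_hi)
        & (v >= rule.ndvi_lo) & (v <= rule.ndvi_hi)
    )
    snow = np.where(np.isnan(v), primary, primary | auxiliary)
    out = np.where(snow, SNOW, NO_SNOW).astype(np.uint8)
    out[np.isnan(s)] = MASKED
    return out


@dataclass
class ThresholdSchedule:
    """Primary NDSI threshold per acquisition period [start, end]."""

    periods: list[tuple[dt.date, dt.date, float]] = field(default_factory=list)

    def threshold_for(self, date: dt.date) -> float:
        for start, end, thr in self.periods:
            if start <= date <= end:
                return thr
        raise KeyError(f"no NDSI threshold configured for {date}")


def buffer_pixels(plot: PlotGeometry, geometry) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels whose center lies within the plot buffer."""
    xs, ys = geometry.pixel_centers()
    inside = (xs - plot.x) ** 2 + (ys - plot.y) ** 2 <= plot.buffer_m**2
    if not geometry.contains_point(plot.x, plot.y):
        raise ValueError(f"plot {plot.plot_id} buffer outside scene extent")
    return np.nonzero(inside)


def plot_snow_from_maps(
    maps: dict[dt.date, np.ndarray],
    plot: PlotGeometry,
    geometry,
    pixel_quorum: float = 0.5,
    window: tuple[dt.date, dt.date] | None = None,
) -> tuple[pd.Series, SnowSeason]:
    """Daily plot flags from classified maps, plus the satellite snow season.

    A day is snow when the fraction of unmasked buffer pixels classified
    snow is >= *pixel_quorum*; all-masked days are unknown.  The season is
    extracted with the same longest-run rule as the sensor pipeline.
    """
    rows, cols = buffer_pixels(plot, geometry)
    if len(rows) == 0:
        raise ValueError(f"no pixel centers fall inside the buffer of {plot.plot_id}")
    flags = {}
    for date, m in maps.items():
        px = m[rows, cols]
        known = px != MASKED
        if not known.any():
            flags[date] = Flag.UNKNOWN
        else:
            frac = (px[known] == SNOW).sum() / known.sum()
            flags[date] = Flag.SNOW if frac >= pixel_quorum else Flag.NO_SNOW
    series = pd.Series(flags).sort_index()
    series.index.name = "date"
    if window is None:
        dates = list(series.index)
        window = (dates[0], dates[-1])
    return series, snow_season(series, window[0], window[1])
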