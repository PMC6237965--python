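"""Georeferenced multiband reflectance scenes.

A :class:`RasterScene` holds the four reflectance bands used throughout the
pipeline (green, red, NIR, SWIR2) as scaled surface reflectance
(stored value = reflectance x 10^4, signed 16-bit) plus a boolean
good-pixel QA mask.  Missing values are ``NODATA`` (-9999).

Scenes are serialised to a headerless row-major int16 binary file with a
JSON sidecar describing geometry, band order, date and tier.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA: int = -9999
SCALE: float = 1e4
BAND_ORDER = ("green", "red", "nir", "swir2")


@dataclass(frozen=True)
class GridGeometry:
    """North-up grid; ``origin`` is the outer corner of the top-left cell."""

    origin_x: float
    origin_y: float
    cell_size: float
    nrows: int
    ncols: int
    crs: str = "local"

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1 or self.cell_size <= 0:
            raise ValueError("invalid grid geometry")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays of shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def contains_point(self, x: float, y: float) -> bool:
        return (
            self.origin_x <= x <= self.origin_x + self.ncols * self.cell_size
            and self.origin_y - self.nrows * self.cell_size <= y <= self.origin_y
        )


@dataclass
class RasterScene:
    """One acquisition: 4 scaled-reflectance bands + QA on a common grid."""

    date: dt.date
    tier: str  # "fine" | "coarse"
    geometry: GridGeometry
    bands: dict[str, np.ndarray] = field(default_factory=dict)
    qa: np.ndarray | None = None  # True = good pixel

    def __post_init__(self) -> None:
        if self.tier not in ("fine", "coarse"):
            raise ValueError(f"tier must be 'fine' or 'coarse', got {self.tier!r}")
        for name, arr in self.bands.items():
            if arr.shape != self.geometry.shape:
                raise ValueError(f"band {name!r} shape {arr.shape} != geometry {self.geometry.shape}")
            self.bands[name] = np.asarray(arr, dtype=np.int16)
        if self.qa is None:
            self.qa = np.ones(self.geometry.shape, dtype=bool)
        elif self.qa.shape != self.geometry.shape:
            raise ValueError("QA mask shape mismatch")
        else:
            self.qa = np.asarray(self.qa, dtype=bool)

    def valid_mask(self, band: str) -> np.ndarray:
        """Good-QA pixels holding a non-nodata value in *band*."""
        return self.qa & (self.bands[band] != NODATA)

    def reflectance(self, band: str) -> np.ndarray:
        """Band as float reflectance in [0, 1]; invalid pixels are NaN."""
        arr = self.bands[band].astype(np.float64) / SCALE
        arr[~self.valid_mask(band)] = np.nan
        return arr

    def copy(self) -> "RasterScene":
        return RasterScene(
            date=self.date,
            tier=self.tier,
            geometry=self.geometry,
            bands={k: v.copy() for k, v in self.bands.items()},
            qa=self.qa.copy(),
        )


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (numpy rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def to_int16(x: np.ndarray, invalid: np.ndarray | None = None) -> np.ndarray:
    out = round_half_away(np.asarray(x, dtype=np.float64))
    out = np.clip(out, np.iinfo(np.int16).min, np.iinfo(np.int16).max)
    out = out.astype(np.int16)
    if invalid is not None:
        out[invalid] = NODATA
    return out


def block_mean(fine: np.ndarray, ratio: int) -> np.ndarray:
    """Mean of each ratio x ratio block of a fine grid (exact nesting)."""
    nr, nc = fine.shape
    if nr % ratio or nc % ratio:
        raise ValueError(f"grid {fine.shape} not divisible by ratio {ratio}")
    return fine.reshape(nr // ratio, ratio, nc // ratio, ratio).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# flat-binary dialect: <stem>.i16 (row-major int16, bands then QA stacked)
# plus <stem>.json sidecar with geometry/date/tier/band order.
# ---------------------------------------------------------------------------

def write_scene(scene: RasterScene, stem: str | Path) -> None:
    stem = Path(stem)
    g = scene.geometry
    planes = [scene.bands[b] for b in BAND_ORDER]
    planes.append(scene.qa.astype(np.int16))
    np.stack(planes).astype("<i2").tofile(stem.with_suffix(".i16"))
    meta = {
        "date": scene.date.isoformat(),
        "tier": scene.tier,
        "bands": list(BAND_ORDER) + ["qa"],
        "dtype": "<i2",
        "nodata": NODATA,
        "geometry": {
            "origin_x": g.origin_x,
            "origin_y": g.origin_y,
            "cell_size": g.cell_size,
            "nrows": g.nrows,
            "ncols": g.ncols,
            "crs": g.crs,
        },
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_scene(stem: str | Path) -> RasterScene:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    g = GridGeometry(**meta["geometry"])
    raw = np.fromfile(stem.with_suffix(".i16"), dtype="<i2")
    names = meta["bands"]
    planes = raw.reshape(len(names), g.nrows, g.ncols)
    bands = {n: planes[i].astype(np.int16) for i, n in enumerate(names) if n != "qa"}
    qa = planes[names.index("qa")].astype(bool) if "qa" in names else None
    return RasterScene(
        date=dt.date.fromisoformat(meta["date"]),
        tier=meta["tier"],
        geometry=g,
        bands=bands,
        qa=qa,
    )
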