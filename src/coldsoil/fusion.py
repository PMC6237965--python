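"""Coarse/fine scene preparation and weighted-neighbourhood fusion.

The predictor assumes the fine (L) and coarse-resampled (M) reflectances
of a same-day pair differ only by a slowly varying bias, so the fine value
on a coarse-only date t_p can be reconstructed per pixel as a weighted sum
of M(t_p) + L(t_k) - M(t_k) over spectrally similar, QA-good neighbours,
weighted by the inverse product of spectral difference S = |L - M| at t_k,
temporal difference T = |M(t_k) - M(t_p)|, and a distance factor
D = 1 + d/A.  Exact zero central differences short-circuit: T = 0 means no
change (prediction = L(t_k)); S = 0 means the sensors agree (prediction =
M(t_p)).  Elsewhere S and T are floored at one scaled-reflectance unit so
exact matches get maximal finite weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .rasters import BAND_ORDER, NODATA, GridGeometry, RasterScene, to_int16


@dataclass
class FusionParams:
    window_half_width: int = 15  # fine pixels
    n_classes: int = 4  # m: similarity threshold = 2 * sigma_band / m
    distance_scale: float | None = None  # A; defaults to window_half_width
    bands: tuple[str, ...] = BAND_ORDER

    def __post_init__(self) -> None:
        if self.window_half_width < 1 or self.n_classes < 1:
            raise ValueError("window_half_width and n_classes must be >= 1")
        if self.distance_scale is None:
            self.distance_scale = float(self.window_half_width)


@dataclass
class FusionPair:
    """Same-day fine scene and coarse scene resampled to the fine grid."""

    fine: RasterScene
    coarse: RasterScene

    def __post_init__(self) -> None:
        if self.fine.date != self.coarse.date:
            raise ValueError("pair scenes must share the acquisition date")
        if self.fine.geometry != self.coarse.geometry:
            raise ValueError("coarse scene must be resampled to the fine geometry first")


def prepare_scene(scene: RasterScene, qa: np.ndarray | None = None) -> RasterScene:
    """Apply a QA mask: bad pixels go to nodata in every band."""
    out = scene.copy()
    if qa is not None:
        if qa.shape != scene.geometry.shape:
            raise ValueError("QA mask geometry mismatch")
        out.qa = out.qa & np.asarray(qa, dtype=bool)
    for band, arr in out.bands.items():
        arr[~out.qa] = NODATA
        good = arr != NODATA
        if (arr[good] < 0).any() or (arr[good] > 10_000).any():
            raise ValueError(f"band {band!r} has values outside the scaled reflectance range")
    return out


def resample_coarse_to_fine(coarse: RasterScene, fine_geometry: GridGeometry) -> RasterScene:
    """Nearest-neighbour resampling of a coarse scene onto a fine grid."""
    cg = coarse.geometry
    xs, ys = fine_geometry.pixel_centers()
    cols = np.floor((xs - cg.origin_x) / cg.cell_size).astype(int)
    rows = np.floor((cg.origin_y - ys) / cg.cell_size).astype(int)
    if (
        cols.max() < 0 or rows.max() < 0
        or cols.min() >= cg.ncols or rows.min() >= cg.nrows
    ):
        raise ValueError("fine grid does not overlap the coarse extent")
    cols = np.clip(cols, 0, cg.ncols - 1)
    rows = np.clip(rows, 0, cg.nrows - 1)
    bands = {b: arr[rows, cols] for b, arr in coarse.bands.items()}
    qa = coarse.qa[rows, cols]
    return RasterScene(date=coarse.date, tier="coarse", geometry=fine_geometry,
                       bands=bands, qa=qa)


def _shift(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """View of arr shifted so out[i, j] = arr[i + dr, j + dc]."""
    out = np.full_like(arr, fill)
    rs = slice(max(0, dr), arr.shape[0] + min(0, dr))
    cs = slice(max(0, dc), arr.shape[1] + min(0, dc))
    rd = slice(max(0, -dr), arr.shape[0] + min(0, -dr))
    cd = slice(max(0, -dc), arr.shape[1] + min(0, -dc))
    out[rd, cd] = arr[rs, cs]
    return out


def starfm_predict(
    pairs: list[FusionPair],
    coarse_tp: RasterScene,
    params: FusionParams | None = None,
) -> RasterScene:
    """Predict the fine scene on the coarse-only date from 1-2 pairs."""
    params = params or FusionParams()
    if not pairs:
        raise ValueError("need at least one fusion pair")
    geom = coarse_tp.geometry
    for p in pairs:
        if p.fine.geometry != geom:
            raise ValueError("all scenes must share the fine geometry")

    out_bands: dict[str, np.ndarray] = {}
    out_valid = np.zeros(geom.shape, dtype=bool)
    A = params.distance_scale
    w = params.window_half_width

    for band in params.bands:
        mp = coarse_tp.bands[band].astype(np.float64)
        mp_ok = coarse_tp.valid_mask(band)
        wsum = np.zeros(geom.shape)
        tsum = np.zeros(geom.shape)
        short = np.full(geom.shape, np.nan)  # zero-difference short-circuit
        fb_sum = np.zeros(geom.shape)
        fb_n = np.zeros(geom.shape)

        per_pair = []
        for pair in pairs:
            lk = pair.fine.bands[band].astype(np.float64)
            mk = pair.coarse.bands[band].astype(np.float64)
            ok = pair.fine.valid_mask(band) & pair.coarse.valid_mask(band) & mp_ok
            sigma = np.std(lk[pair.fine.valid_mask(band)]) if pair.fine.valid_mask(band).any() else 0.0
            thresh = sigma * 2.0 / params.n_classes
            per_pair.append((lk, mk, ok, thresh))

            # central-pixel exact-zero rules; first pair satisfying wins,
            # T-rule (no temporal change) before S-rule (sensors agree)
            zt = ok & (np.abs(mk - mp) == 0)
            zs = ok & (np.abs(lk - mk) == 0)
            short = np.where(zt & np.isnan(short), lk, short)
            short = np.where(zs & np.isnan(short), mp, short)

            # central fallback term
            fb_sum += np.where(ok, lk + mp - mk, 0.0)
            fb_n += ok

        for pair_vals in per_pair:
            lk, mk, ok, thresh = pair_vals
            s_all = np.abs(lk - mk)
            t_all = np.abs(mk - mp)
            for dr in range(-w, w + 1):
                for dc in range(-w, w + 1):
                    cand_ok = _shift(ok, dr, dc, False)
                    lk_n = _shift(lk, dr, dc, 0.0)
                    sim = np.abs(lk_n - lk) <= thresh
                    use = cand_ok & ok & sim
                    if not use.any():
                        continue
                    s = np.maximum(_shift(s_all, dr, dc, 1.0), 1.0)
                    t = np.maximum(_shift(t_all, dr, dc, 1.0), 1.0)
                    d = 1.0 + np.hypot(dr, dc) / A
                    wt = np.where(use, 1.0 / (s * t * d), 0.0)
                    term = lk_n + _shift(mp, dr, dc, 0.0) - _shift(mk, dr, dc, 0.0)
                    wsum += wt
                    tsum += wt * term

        pred = np.full(geom.shape, np.nan)
        have_w = wsum > 0
        pred[have_w] = tsum[have_w] / wsum[have_w]
        have_fb = (fb_n > 0) & ~have_w
        pred[have_fb] = fb_sum[have_fb] / fb_n[have_fb]
        pred = np.where(np.isnan(short), pred, short)
        valid = ~np.isnan(pred)
        out_bands[band] = to_int16(np.nan_to_num(pred), invalid=~valid)
        out_valid |= valid

    return RasterScene(date=coarse_tp.date, tier="fine", geometry=geom,
                       bands=out_bands, qa=out_valid)


def assess_fusion_accuracy(predicted: RasterScene, actual: RasterScene,
                           bands: tuple[str, ...] = BAND_ORDER) -> dict[str, dict[str, float]]:
    """Per-band Spearman rho / RMSE / MAE over jointly valid pixels."""
    if predicted.geometry != actual.geometry:
        raise ValueError("scenes must share geometry")
    report: dict[str, dict[str, float]] = {}
    for band in bands:
        both = predicted.valid_mask(band) & actual.valid_mask(band)
        if not both.any():
            raise ValueError(f"no jointly valid pixels in band {band!r}")
        p = predicted.bands[band][both].astype(float)
        a = actual.bands[band][both].astype(float)
        if np.ptp(p) == 0 and np.ptp(a) == 0:
            rho = 1.0 if np.array_equal(p, a) else float("nan")
        else:
            rho = float(scipy.stats.spearmanr(p, a).statistic)
        report[band] = {
            "spearman_rho": rho,
            "rmse": float(np.sqrt(np.mean((p - a) ** 2))),
            "mae": float(np.mean(np.abs(p - a))),
            "n": int(both.sum()),
        }
    return report
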