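import datetime as dt

import numpy as np
import pytest

from coldsoil.fusion import (
    FusionPair,
    FusionParams,
    assess_fusion_accuracy,
    prepare_scene,
    resample_coarse_to_fine,
    starfm_predict,
)
from coldsoil.rasters import NODATA, GridGeometry, RasterScene

from conftest import toy_scene

T_K = dt.date(2014, 1, 1)
T_P = dt.date(2014, 1, 15)
BANDS = ("green", "red", "nir", "swir2")


def scene_from(vals, date=T_K, tier="fine", qa=None, geom=None):
    vals = np.asarray(vals, dtype=np.int16)
    if geom is None:
        geom = GridGeometry(0.0, vals.shape[0] * 30.0, 30.0, vals.shape[0], vals.shape[1])
    return RasterScene(date=date, tier=tier, geometry=geom,
                       bands={b: vals.copy() for b in BANDS}, qa=qa)


# ---------------------------------------------------------------------------
# brute-force oracle: same weighting, written as explicit per-pixel loops
# ---------------------------------------------------------------------------

def starfm_oracle(pairs, coarse_tp, params):
    geom = coarse_tp.geometry
    nr, nc = geom.shape
    w, A, m = params.window_half_width, params.distance_scale, params.n_classes
    out = {}
    for band in params.bands:
        mp = coarse_tp.bands[band].astype(float)
        mp_ok = coarse_tp.valid_mask(band)
        info = []
        for pair in pairs:
            lk = pair.fine.bands[band].astype(float)
            mk = pair.coarse.bands[band].astype(float)
            ok = pair.fine.valid_mask(band) & pair.coarse.valid_mask(band) & mp_ok
            fv = pair.fine.valid_mask(band)
            sigma = lk[fv].std() if fv.any() else 0.0
            info.append((lk, mk, ok, sigma * 2.0 / m))
        pred = np.full((nr, nc), np.nan)
        for i in range(nr):
            for j in range(nc):
                # central exact-zero short-circuits, T-rule then S-rule per pair
                done = False
                for lk, mk, ok, _ in info:
                    if ok[i, j] and mk[i, j] == mp[i, j]:
                        pred[i, j] = lk[i, j]
                        done = True
                        break
                    if ok[i, j] and lk[i, j] == mk[i, j]:
                        pred[i, j] = mp[i, j]
                        done = True
                        break
                if done:
                    continue
                wsum = tsum = 0.0
                for lk, mk, ok, thresh in info:
                    if not ok[i, j]:
                        continue
                    for p in range(max(0, i - w), min(nr, i + w + 1)):
                        for q in range(max(0, j - w), min(nc, j + w + 1)):
                            if not ok[p, q]:
                                continue
                            if abs(lk[p, q] - lk[i, j]) > thresh:
                                continue
                            s = max(abs(lk[p, q] - mk[p, q]), 1.0)
                            t = max(abs(mk[p, q] - mp[p, q]), 1.0)
                            d = 1.0 + np.hypot(p - i, q - j) / A
                            wt = 1.0 / (s * t * d)
                            wsum += wt
                            tsum += wt * (lk[p, q] + mp[p, q] - mk[p, q])
                if wsum > 0:
                    pred[i, j] = tsum / wsum
                else:
                    fb = [lk[i, j] + mp[i, j] - mk[i, j] for lk, mk, ok, _ in info if ok[i, j]]
                    if fb:
                        pred[i, j] = float(np.mean(fb))
        invalid = np.isnan(pred)
        filled = np.where(invalid, 0.0, pred)
        vals = (np.sign(filled) * np.floor(np.abs(filled) + 0.5)).astype(np.int16)
        vals[invalid] = NODATA
        out[band] = vals
    return out


class TestPrepareScene:
    def test_all_good_identity(self):
        sc = toy_scene(np.full((4, 4), 1234))
        out = prepare_scene(sc, np.ones((4, 4), dtype=bool))
        assert np.array_equal(out.bands["green"], sc.bands["green"])

    def test_all_bad_all_nodata(self):
        sc = toy_scene(np.full((4, 4), 1234))
        out = prepare_scene(sc, np.zeros((4, 4), dtype=bool))
        for b in BANDS:
            assert (out.bands[b] == NODATA).all()

    def test_cloud_patch_count(self):
        sc = toy_scene(np.full((10, 10), 500))
        qa = np.ones((10, 10), dtype=bool)
        qa[2:7, 3:8] = False  # 25 pixels
        out = prepare_scene(sc, qa)
        for b in BANDS:
            assert int((out.bands[b] == NODATA).sum()) == 25

    def test_out_of_range_rejected(self):
        sc = toy_scene(np.full((4, 4), 1000))
        sc.bands["red"][0, 0] = 12_000
        with pytest.raises(ValueError, match="range"):
            prepare_scene(sc)

    def test_qa_shape_mismatch(self):
        sc = toy_scene(np.full((4, 4), 1000))
        with pytest.raises(ValueError):
            prepare_scene(sc, np.ones((3, 3), dtype=bool))


class TestResample:
    def test_nested_replication(self):
        cg = GridGeometry(0, 270, 90, 3, 3)
        cvals = (np.arange(9) * 100).reshape(3, 3).astype(np.int16)
        coarse = RasterScene(date=T_K, tier="coarse", geometry=cg,
                             bands={b: cvals.copy() for b in BANDS})
        fg = GridGeometry(0, 270, 30, 9, 9)
        fine = resample_coarse_to_fine(coarse, fg)
        for r in range(9):
            for c in range(9):
                assert fine.bands["green"][r, c] == cvals[r // 3, c // 3]

    def test_constant_stays_constant(self):
        cg = GridGeometry(0, 300, 100, 3, 3)
        coarse = RasterScene(date=T_K, tier="coarse", geometry=cg,
                             bands={b: np.full((3, 3), 777, np.int16) for b in BANDS})
        fine = resample_coarse_to_fine(coarse, GridGeometry(0, 300, 30, 10, 10))
        assert (fine.bands["green"] == 777).all()

    def test_checkerboard_vs_brute_force(self):
        cg = GridGeometry(0, 240, 60, 4, 4)
        cvals = np.indices((4, 4)).sum(0) % 2 * 1000
        coarse = RasterScene(date=T_K, tier="coarse", geometry=cg,
                             bands={b: cvals.astype(np.int16) for b in BANDS})
        fg = GridGeometry(0, 240, 30, 8, 8)
        fine = resample_coarse_to_fine(coarse, fg)
        xs, ys = fg.pixel_centers()
        for r in range(8):
            for c in range(8):
                cr = int((240 - ys[r, c]) // 60)
                cc = int(xs[r, c] // 60)
                assert fine.bands["red"][r, c] == cvals[cr, cc]

    def test_disjoint_extents_raise(self):
        cg = GridGeometry(0, 100, 50, 2, 2)
        coarse = RasterScene(date=T_K, tier="coarse", geometry=cg,
                             bands={b: np.zeros((2, 2), np.int16) for b in BANDS})
        with pytest.raises(ValueError, match="overlap"):
            resample_coarse_to_fine(coarse, GridGeometry(10_000, 100, 30, 3, 3))


class TestStarfmIdentities:
    def test_temporal_identity(self):
        rng = np.random.default_rng(0)
        L = rng.integers(500, 5000, (9, 9)).astype(np.int16)
        Mk = (L + rng.integers(-300, 300, (9, 9))).astype(np.int16)
        pair = FusionPair(fine=scene_from(L), coarse=scene_from(Mk, tier="coarse"))
        pred = starfm_predict([pair], scene_from(Mk, date=T_P, tier="coarse"),
                              FusionParams(window_half_width=3))
        for b in BANDS:
            assert np.array_equal(pred.bands[b], L)

    def test_uniform_shift(self):
        L = np.full((7, 7), 2000, np.int16)
        Mk = np.full((7, 7), 2150, np.int16)
        pair = FusionPair(fine=scene_from(L), coarse=scene_from(Mk, tier="coarse"))
        pred = starfm_predict([pair], scene_from(Mk + 500, date=T_P, tier="coarse"),
                              FusionParams(window_half_width=3))
        for b in BANDS:
            assert np.array_equal(pred.bands[b], L + 500)

    def test_all_nodata_pixel_stays_nodata(self):
        L = np.full((5, 5), 2000, np.int16)
        qa = np.ones((5, 5), dtype=bool)
        qa[2, 2] = False
        pair = FusionPair(fine=scene_from(L, qa=qa), coarse=scene_from(L, tier="coarse", qa=qa))
        ctp = scene_from(L, date=T_P, tier="coarse", qa=qa)
        pred = starfm_predict([pair], ctp, FusionParams(window_half_width=1))
        # neighbours carry it, but a fully isolated nodata input set cannot
        all_bad = np.zeros((5, 5), dtype=bool)
        pair2 = FusionPair(fine=scene_from(L, qa=all_bad), coarse=scene_from(L, tier="coarse", qa=all_bad))
        pred2 = starfm_predict([pair2], scene_from(L, date=T_P, tier="coarse", qa=all_bad),
                               FusionParams(window_half_width=1))
        assert (pred2.bands["green"] == NODATA).all()
        assert pred.bands["green"][0, 0] != NODATA

    def test_requires_pairs(self):
        with pytest.raises(ValueError):
            starfm_predict([], scene_from(np.zeros((3, 3)), tier="coarse"))


class TestStarfmOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_single_pair_9x9(self, seed):
        rng = np.random.default_rng(seed)
        def rand_scene(date, tier="fine"):
            vals = rng.integers(200, 8000, (9, 9)).astype(np.int16)
            qa = rng.random((9, 9)) > 0.1
            return scene_from(vals, date=date, tier=tier, qa=qa)

        params = FusionParams(window_half_width=2, n_classes=4)
        pair = FusionPair(fine=rand_scene(T_K), coarse=rand_scene(T_K, "coarse"))
        ctp = rand_scene(T_P, "coarse")
        got = starfm_predict([pair], ctp, params)
        want = starfm_oracle([pair], ctp, params)
        for b in BANDS:
            assert np.array_equal(got.bands[b], want[b]), b

    @pytest.mark.parametrize("seed", [10, 11])
    def test_two_pairs_with_gaps(self, seed):
        rng = np.random.default_rng(seed)
        def rand_scene(date, tier="fine"):
            vals = rng.integers(200, 8000, (7, 7)).astype(np.int16)
            qa = rng.random((7, 7)) > 0.2
            return scene_from(vals, date=date, tier=tier, qa=qa)

        params = FusionParams(window_half_width=3, n_classes=3)
        pairs = [
            FusionPair(fine=rand_scene(T_K), coarse=rand_scene(T_K, "coarse")),
            FusionPair(fine=rand_scene(dt.date(2014, 2, 1)),
                       coarse=rand_scene(dt.date(2014, 2, 1), "coarse")),
        ]
        ctp = rand_scene(T_P, "coarse")
        got = starfm_predict(pairs, ctp, params)
        want = starfm_oracle(pairs, ctp, params)
        for b in BANDS:
            assert np.array_equal(got.bands[b], want[b]), b

    def test_boundedness(self):
        rng = np.random.default_rng(20)
        # odd values everywhere prevent exact-zero short-circuits
        L = (rng.integers(200, 4000, (7, 7)) * 2 + 1).astype(np.int16)
        Mk = (rng.integers(200, 4000, (7, 7)) * 2).astype(np.int16)
        Mp = (Mk + rng.integers(50, 400, (7, 7)) * 2 + 1).astype(np.int16)
        params = FusionParams(window_half_width=3)
        pair = FusionPair(fine=scene_from(L), coarse=scene_from(Mk, tier="coarse"))
        pred = starfm_predict([pair], scene_from(Mp, date=T_P, tier="coarse"), params)
        term = L.astype(float) + Mp.astype(float) - Mk.astype(float)
        assert (pred.bands["green"] >= np.floor(term.min())).all()
        assert (pred.bands["green"] <= np.ceil(term.max())).all()


class TestAccuracy:
    def test_perfect(self):
        sc = toy_scene(np.arange(9).reshape(3, 3) * 100)
        rep = assess_fusion_accuracy(sc, sc)
        for b in BANDS:
            assert rep[b]["spearman_rho"] == 1.0
            assert rep[b]["rmse"] == 0.0 and rep[b]["mae"] == 0.0

    def test_constant_offset(self):
        a = toy_scene(np.arange(9).reshape(3, 3) * 100)
        b = toy_scene(np.arange(9).reshape(3, 3) * 100 + 100)
        rep = assess_fusion_accuracy(b, a)
        for band in BANDS:
            assert rep[band]["spearman_rho"] == 1.0
            assert rep[band]["rmse"] == pytest.approx(100.0)
            assert rep[band]["mae"] == pytest.approx(100.0)

    def test_three_pixel_toy(self):
        p = toy_scene(np.array([[1, 2, 3]]))
        a = toy_scene(np.array([[3, 2, 1]]))
        rep = assess_fusion_accuracy(p, a)
        assert rep["green"]["spearman_rho"] == pytest.approx(-1.0)
        assert rep["green"]["rmse"] == pytest.approx(np.sqrt(8 / 3))
        assert rep["green"]["mae"] == pytest.approx(4 / 3)

    def test_no_overlap_raises(self):
        a = toy_scene(np.full((2, 2), 5), qa=np.zeros((2, 2), dtype=bool))
        b = toy_scene(np.full((2, 2), 5))
        with pytest.raises(ValueError, match="valid"):
            assess_fusion_accuracy(a, b)
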