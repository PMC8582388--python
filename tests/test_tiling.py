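"""Otsu thresholding, tissue detection, and sliding-window tile enumeration."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.transform import downscale_local_mean

import slideminer as sm
from slideminer.tiling import TissueMask, grayscale


def brute_force_otsu(hist: np.ndarray) -> float:
    """Independent oracle: exhaustive between-class-variance search by loop.

    Same definitional tie rule (plateau midpoint), independent computation.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_val, best_cuts = -1.0, []
    for t in range(255):  # class 0 = bins 0..t, class 1 = bins t+1..255
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        val = w0 * w1 * (mu0 - mu1) ** 2
        if val > best_val * (1 + 1e-12):
            best_val, best_cuts = val, [t]
        elif np.isclose(val, best_val, rtol=0, atol=best_val * 1e-12):
            best_cuts.append(t)
    return (best_cuts[0] + best_cuts[-1]) / 2.0


class TestOtsu:
    def test_two_delta_masses(self):
        hist = np.zeros(256)
        hist[50], hist[200] = 30, 70
        thr, degenerate = sm.otsu_threshold(hist)
        assert not degenerate
        assert 50 < thr < 200

    def test_matches_exhaustive_search_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            hist = rng.integers(0, 50, size=256).astype(float)
            hist[rng.random(256) < 0.7] = 0
            if hist.sum() == 0 or (hist > 0).sum() < 2:
                continue
            thr, _ = sm.otsu_threshold(hist)
            assert thr == pytest.approx(brute_force_otsu(hist), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        hist = np.zeros(256)
        idx = rng.choice(256, size=rng.integers(2, 40), replace=False)
        hist[idx] = rng.integers(1, 1000, size=len(idx))
        thr, _ = sm.otsu_threshold(hist)
        assert thr == pytest.approx(brute_force_otsu(hist), abs=1e-9)

    def test_bimodal_gaussian_mixture(self):
        rng = np.random.default_rng(0)
        samples = np.concatenate(
            [rng.normal(80, 10, 20000), rng.normal(220, 10, 20000)]
        )
        hist, _ = np.histogram(np.clip(samples, 0, 255), bins=256, range=(0, 256))
        thr, _ = sm.otsu_threshold(hist)
        assert 110 < thr < 190

    def test_single_bin_degenerate(self):
        hist = np.zeros(256)
        hist[128] = 10
        thr, degenerate = sm.otsu_threshold(hist)
        assert degenerate and thr == 128

    def test_empty_histogram_error(self):
        with pytest.raises(ValueError):
            sm.otsu_threshold(np.zeros(256))


class TestDetectTissue:
    def test_all_white_slide_gives_empty_mask(self):
        rec = sm.SlideRecord("white", None, 20, 0)
        rec._image = np.full((256, 256, 3), 255, dtype=np.uint8)
        mask = sm.detect_tissue(rec, 8)
        assert mask.degenerate and not mask.mask.any()

    def test_mask_matches_ground_truth(self, positive_slide):
        mask = sm.detect_tissue(positive_slide, 8)
        gt = downscale_local_mean(
            positive_slide.ground_truth_tissue_mask.astype(float), (8, 8)
        ) > 0.5
        inter = (mask.mask & gt).sum()
        union = (mask.mask | gt).sum()
        assert inter / union >= 0.9

    def test_area_invariant_to_downsample(self, positive_slide):
        a4 = sm.detect_tissue(positive_slide, 4).tissue_area_level0
        a8 = sm.detect_tissue(positive_slide, 8).tissue_area_level0
        assert abs(a4 - a8) / a4 <= 0.05

    def test_mask_shape_is_ceil_of_dims(self, positive_slide):
        mask = sm.detect_tissue(positive_slide, 7)
        h, w = positive_slide.load_image().shape[:2]
        assert mask.mask.shape == (int(np.ceil(h / 7)), int(np.ceil(w / 7)))


def full_mask(size: int, ds: int = 1) -> TissueMask:
    return TissueMask(mask=np.ones((size // ds, size // ds), bool), downsample_factor=ds)


class TestEnumerateTiles:
    def test_grid_count_on_full_tissue(self):
        tiles = sm.enumerate_tiles(full_mask(1024), 512, 256, min_tissue_fraction=0.0,
                                   magnification=20, scan_magnification=20,
                                   slide_shape=(1024, 1024))
        assert len(tiles) == 9  # 3x3 lattice of in-bounds positions

    def test_stride_defaults_to_half_tile(self):
        for tile in (512, 224):
            tiles = sm.enumerate_tiles(full_mask(2 * tile), tile, None, 0.0,
                                       magnification=20, scan_magnification=20,
                                       slide_shape=(2 * tile, 2 * tile))
            xs = sorted({t.x for t in tiles})
            assert xs == [0, tile // 2, tile]

    def test_empty_mask_gives_no_tiles(self):
        mask = TissueMask(np.zeros((32, 32), bool), downsample_factor=8)
        assert sm.enumerate_tiles(mask, 64, 32, 0.1, magnification=20,
                                  scan_magnification=20, slide_shape=(256, 256)) == []

    def test_row_major_order_and_stride_multiples(self, positive_slide):
        mask = sm.detect_tissue(positive_slide, 8)
        tiles = sm.enumerate_tiles(mask, 64, 32, 0.1, magnification=20,
                                   scan_magnification=20, slide_shape=(320, 320))
        assert tiles
        keys = [(t.y, t.x) for t in tiles]
        assert keys == sorted(keys)
        assert all(t.x % 32 == 0 and t.y % 32 == 0 for t in tiles)

    def test_oversized_tile_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="exceeds slide bounds"):
            tiles = sm.enumerate_tiles(full_mask(128), 512, 256, 0.0,
                                       magnification=20, scan_magnification=20,
                                       slide_shape=(128, 128))
        assert tiles == []

    def test_tissue_fraction_filter(self, positive_slide):
        mask = sm.detect_tissue(positive_slide, 8)
        loose = sm.enumerate_tiles(mask, 64, 32, 0.0, magnification=20,
                                   scan_magnification=20, slide_shape=(320, 320))
        strict = sm.enumerate_tiles(mask, 64, 32, 0.9, magnification=20,
                                    scan_magnification=20, slide_shape=(320, 320))
        assert set(strict) <= set(loose)
        assert len(strict) < len(loose)

    def test_coverage_of_tissue_pixels(self, positive_slide):
        """At stride T/2 with no fraction cutoff, interior tissue is covered >= 4x."""
        T = 64
        mask = sm.detect_tissue(positive_slide, 8)
        tiles = sm.enumerate_tiles(mask, T, T // 2, 0.0, magnification=20,
                                   scan_magnification=20, slide_shape=(320, 320))
        cover = np.zeros((320, 320), int)
        for t in tiles:
            cover[t.y : t.y + T, t.x : t.x + T] += 1
        tissue = positive_slide.ground_truth_tissue_mask
        interior = tissue.copy()
        interior[: T, :] = interior[-T:, :] = False
        interior[:, : T] = interior[:, -T:] = False
        assert (cover[interior] >= 4).all()
        assert (cover[interior] >= 1).all()


class TestExtractTile:
    def test_identity_crop_at_scan_magnification(self, positive_slide):
        coord = sm.TileCoord(32, 64, 64, 20)
        tile = sm.extract_tile(positive_slide, coord)
        expected = positive_slide.load_image()[64:128, 32:96] / 255.0
        assert np.allclose(tile, expected)

    def test_downsampled_tile_sources_double_region(self, positive_slide):
        """A x10 tile of size 64 from a x20 scan comes from a 128x128 region."""
        coord = sm.TileCoord(0, 0, 64, 10)
        tile = sm.extract_tile(positive_slide, coord)
        assert tile.shape == (64, 64, 3)
        region = positive_slide.load_image()[0:128, 0:128].astype(float)
        expected = downscale_local_mean(region, (2, 2, 1)) / 255.0
        assert np.allclose(tile, expected)

    def test_constant_region_stays_constant(self):
        rec = sm.SlideRecord("const", None, 20, 0)
        rec._image = np.full((128, 128, 3), 77, dtype=np.uint8)
        tile = sm.extract_tile(rec, sm.TileCoord(0, 0, 32, 10))
        assert np.allclose(tile, 77 / 255.0)

    def test_out_of_bounds_raises(self, positive_slide):
        with pytest.raises(ValueError, match="out of bounds"):
            sm.extract_tile(positive_slide, sm.TileCoord(300, 300, 64, 20))


def test_grayscale_luminance_weights():
    rgb = np.zeros((1, 1, 3))
    rgb[0, 0] = [100, 200, 50]
    assert grayscale(rgb)[0, 0] == pytest.approx(0.299 * 100 + 0.587 * 200 + 0.114 * 50)
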