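import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import helpers
from slidemil import tiling_qc as tq


@pytest.fixture()
def cfg():
    return tq.QCConfig()


class TestTissueMask:
    def test_uniform_white_slide_has_no_tissue(self):
        img = np.full((1000, 1000, 3), 255, dtype=np.uint8)
        mask = tq.compute_tissue_mask(img, 10)
        assert mask.mask.sum() == 0

    def test_half_white_half_gray_foreground_covers_gray_half(self):
        img = np.full((400, 400, 3), 255, dtype=np.uint8)
        img[:, 200:] = 128
        mask = tq.compute_tissue_mask(img, 10)
        oracle = helpers.brute_force_mask(img, 10)
        assert np.array_equal(mask.mask, oracle)
        # gray (darker) half is tissue
        assert mask.mask[:, 20:].all()
        assert not mask.mask[:, :20].any()

    def test_mask_dimensions_are_ceil_of_tenth(self):
        img = np.full((4000, 5000, 3), 255, dtype=np.uint8)
        img[:100, :100] = 0
        mask = tq.compute_tissue_mask(img, 10)
        assert mask.mask.shape == (400, 500)
        # non-divisible dims round up
        mask2 = tq.compute_tissue_mask(img[:3995, :4997], 10)
        assert mask2.mask.shape == (400, 500)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            tq.compute_tissue_mask(np.zeros((0, 0, 3), dtype=np.uint8), 10)


class TestGrid:
    @pytest.mark.parametrize("w,h,mag,expect_n,expect_side", [
        (2048, 1024, "40x", 8, 512),
        (2049, 1024, "40x", 8, 512),   # border column dropped
        (4096, 4096, "20x", 16, 1024),
        (511, 511, "40x", 0, 512),     # slide smaller than one patch
    ])
    def test_grid_counts_and_side(self, cfg, w, h, mag, expect_n, expect_side):
        slide = tq.SlideInfo("s", w, h)
        records = tq.generate_grid(slide, cfg, mag)
        assert len(records) == expect_n
        assert all(r.side_px == expect_side for r in records)
        assert all(r.x % r.side_px == 0 and r.y % r.side_px == 0
                   for r in records)

    def test_row_major_order_and_40x_coordinates(self, cfg):
        records = tq.generate_grid(tq.SlideInfo("s", 2048, 1024), cfg, "40x")
        assert [(r.x, r.y) for r in records[:4]] == [
            (0, 0), (512, 0), (1024, 0), (1536, 0)]
        assert {r.y for r in records} == {0, 512}

    @given(w=st.integers(1, 5000), h=st.integers(1, 5000))
    @settings(max_examples=40, deadline=None)
    def test_grid_covers_slide_up_to_border_strips(self, w, h):
        cfg = tq.QCConfig()
        records = tq.generate_grid(tq.SlideInfo("s", w, h), cfg, "40x")
        n_cols, n_rows = w // 512, h // 512
        assert len(records) == n_cols * n_rows
        if records:
            assert max(r.x + r.side_px for r in records) <= w
            assert max(r.y + r.side_px for r in records) <= h
            # footprints tile [0, 512*n_cols) x [0, 512*n_rows) exactly
            assert len({(r.x, r.y) for r in records}) == len(records)


class TestFilters:
    def test_tissue_boundary_is_inclusive(self, cfg):
        # footprint half inside a rectangular foreground -> fraction 0.5
        mask = np.zeros((52, 52), dtype=bool)
        mask[:, 26:] = True
        rec = tq.PatchRecord("s", 0, 0, 520, "40x")
        assert tq.tissue_filter(rec, tq.TissueMask(mask, 10), cfg)
        assert rec.tissue_fraction == 0.5
        # exactly at min_tissue_fraction passes
        cfg2 = tq.QCConfig(min_tissue_fraction=0.5)
        assert tq.tissue_filter(rec, tq.TissueMask(mask, 10), cfg2)

    def test_zero_tissue_fails(self, cfg):
        mask = tq.TissueMask(np.zeros((52, 52), dtype=bool), 10)
        rec = tq.PatchRecord("s", 0, 0, 512, "40x")
        assert not tq.tissue_filter(rec, mask, cfg)
        assert rec.tissue_fraction == 0.0

    def test_background_fraction_thresholds(self, cfg):
        white = np.full((64, 64, 3), 255, dtype=np.uint8)
        assert not tq.background_filter(white, cfg)
        gray = np.full((64, 64, 3), 128, dtype=np.uint8)
        assert tq.background_filter(gray, cfg)

    def test_background_95_percent_near_white_excluded(self, cfg):
        # 95% of pixels at (230,230,230), rest (100,100,100)
        px = np.full((100, 100, 3), 230, dtype=np.uint8)
        px[:5, :] = 100
        rec = tq.PatchRecord("s", 0, 0, 100, "40x")
        assert not tq.background_filter(px, cfg, rec)
        assert rec.background_fraction == 0.95

    def test_white_rule_requires_all_channels(self, cfg):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[...] = (255, 255, 100)  # one channel below threshold
        assert tq.background_fraction_of(px, cfg) == 0.0

    def test_saturation_gray_patch_excluded(self, cfg):
        gray = np.full((32, 32, 3), 128, dtype=np.uint8)
        assert not tq.saturation_filter(gray, cfg)

    def test_saturation_pink_patch_kept(self, cfg):
        pink = np.zeros((32, 32, 3), dtype=np.uint8)
        pink[...] = (230, 100, 180)
        rec = tq.PatchRecord("s", 0, 0, 32, "40x")
        assert tq.saturation_filter(pink, cfg, rec)
        assert rec.saturation_stat == pytest.approx((230 - 100) / 230, abs=1e-9)

    def test_saturation_boundary_is_kept(self):
        # mean S exactly at the threshold -> keep (exclusion is strict <)
        cfg = tq.QCConfig(saturation_threshold=0.5)
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        px[...] = (200, 100, 100)  # S = 100/200 = 0.5 exactly
        assert tq.saturation_filter(px, cfg)

    def test_saturation_all_background_is_degenerate_exclusion(self, cfg):
        white = np.full((8, 8, 3), 255, dtype=np.uint8)
        assert not tq.saturation_filter(white, cfg)

    def test_blur_constant_patch_excluded(self, cfg):
        flat = np.full((64, 64, 3), 90, dtype=np.uint8)
        rec = tq.PatchRecord("s", 0, 0, 64, "40x")
        assert not tq.blur_filter(flat, cfg, rec)
        assert rec.blur_score == 0.0

    def test_blur_checkerboard_matches_convolution_oracle(self, cfg):
        side = 64
        board = np.indices((side, side)).sum(axis=0) % 2 * 255
        px = np.stack([board] * 3, axis=-1).astype(np.uint8)
        score = tq.blur_score_of(px)
        g = helpers._gray01(px) * 255.0
        p = np.pad(g, 1, mode="symmetric")
        lap = (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
               - 4.0 * p[1:-1, 1:-1])
        assert score == pytest.approx(lap.var(), rel=1e-12)

    def test_gaussian_blur_strictly_reduces_focus_measure(self, rng):
        from scipy.ndimage import gaussian_filter
        sharp = rng.integers(0, 256, (128, 128, 3)).astype(np.float64)
        blurred = np.stack([gaussian_filter(sharp[..., c], 3.0)
                            for c in range(3)], axis=-1)
        assert (tq.blur_score_of(blurred.astype(np.uint8))
                < tq.blur_score_of(sharp.astype(np.uint8)))


class TestExtractPatch:
    def test_40x_crop_dimensions(self, cfg, rng):
        img = rng.integers(0, 256, (1024, 1024, 3), dtype=np.uint8)
        rec = tq.PatchRecord("s", 512, 0, 512, "40x")
        out = tq.extract_patch(img, rec, cfg)
        assert out.shape == (512, 512, 3)
        assert np.array_equal(out, img[0:512, 512:1024])

    def test_20x_constant_region_preserved(self, cfg):
        img = np.full((1024, 1024, 3), 77, dtype=np.uint8)
        rec = tq.PatchRecord("s", 0, 0, 1024, "20x")
        out = tq.extract_patch(img, rec, cfg)
        assert out.shape == (512, 512, 3)
        assert (out == 77).all()

    def test_20x_periodic_pattern_area_average_rounds_half_even(self, cfg):
        img = np.zeros((1024, 1024, 3), dtype=np.uint8)
        img[::2, ::2] = 255
        img[1::2, 1::2] = 255  # every 2x2 block averages to 127.5
        rec = tq.PatchRecord("s", 0, 0, 1024, "20x")
        out = tq.extract_patch(img, rec, cfg)
        assert (out == 128).all()  # round-half-to-even: 127.5 -> 128

    def test_out_of_bounds_record_raises(self, cfg):
        img = np.zeros((512, 512, 3), dtype=np.uint8)
        with pytest.raises(IndexError):
            tq.extract_patch(img, tq.PatchRecord("s", 256, 0, 512, "40x"), cfg)


class TestPipeline:
    def test_fixture_stage_counts(self, qc_results):
        records, report = qc_results
        assert report.counts() == [12, 8, 8, 8, 6]
        assert sum(r.qc_pass for r in records) == 6

    def test_all_white_slide_survives_nothing(self, cfg):
        img = np.full((1024, 1024, 3), 255, dtype=np.uint8)
        records, report = tq.run_qc_pipeline(img, "blank", cfg, "40x")
        assert report.counts()[-1] == 0
        assert all(not r.qc_pass for r in records)

    def test_monotone_stage_counts_and_first_fail(self, qc_results):
        records, report = qc_results
        counts = report.counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        for r in records:
            assert r.qc_pass == (r.qc_fail_stage is None)
            if r.qc_pass:
                assert r.tissue_fraction >= 0.10
                assert r.background_fraction <= 0.90
                assert r.blur_score >= 50.0

    def test_pipeline_is_deterministic(self, fixture_slide, cfg):
        _, img, _ = fixture_slide
        rec1, rep1 = tq.run_qc_pipeline(img, "f", cfg, "40x")
        rec2, rep2 = tq.run_qc_pipeline(img, "f", cfg, "40x")
        assert rep1.counts() == rep2.counts()
        assert [(r.x, r.y, r.qc_pass, r.qc_fail_stage) for r in rec1] == \
               [(r.x, r.y, r.qc_pass, r.qc_fail_stage) for r in rec2]

    def test_manifest_round_trip(self, qc_results):
        records, _ = qc_results
        df = tq.records_to_manifest(records)
        back = tq.manifest_to_records(df)
        assert [(r.x, r.y, r.qc_pass, r.qc_fail_stage) for r in back] == \
               [(r.x, r.y, r.qc_pass, r.qc_fail_stage) for r in records]
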