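"""Saturation channel, baseline correction, thresholding and mask chain."""

import numpy as np
import pytest
from scipy import stats
from skimage import color
from skimage.filters import threshold_multiotsu

from bruise_evolve import extraction as ex
from bruise_evolve.phantom import render_series

from conftest import small_config
from oracles import (
    bfs_largest_component,
    brute_force_three_class_otsu,
    fill_holes_by_complement,
)


class TestSaturationChannel:
    def test_reference_pixels(self):
        img = np.array(
            [[[128, 128, 128], [0, 0, 255], [60, 90, 180]]], dtype=np.uint8
        )
        np.testing.assert_array_equal(
            ex.to_saturation_channel(img)[0], [0, 255, 170]
        )

    def test_matches_skimage_hsv(self, rng):
        img = rng.integers(0, 256, size=(40, 30, 3), dtype=np.uint8)
        ours = ex.to_saturation_channel(img).astype(int)
        ref = np.rint(color.rgb2hsv(img)[..., 1] * 255).astype(int)
        # identical up to rounding of values landing exactly on .5
        assert np.abs(ours - ref).max() <= 1
        assert (ours != ref).mean() < 0.01

    def test_wrong_shape_rejected(self):
        with pytest.raises(ex.InputError):
            ex.to_saturation_channel(np.zeros((5, 5), dtype=np.uint8))


class TestOffsets:
    def test_identical_frames_zero_offsets(self):
        frames = [np.full((20, 20), 77, dtype=np.uint8)] * 5
        offs = ex.compute_offsets(frames, (2, 2, 10, 10))
        np.testing.assert_allclose(offs.offsets, 0.0)

    def test_constant_shift_recovered(self):
        base = np.arange(400, dtype=np.uint8).reshape(20, 20) // 2
        frames = [base, np.clip(base + 12, 0, 255).astype(np.uint8)]
        offs = ex.compute_offsets(frames, (0, 0, 20, 10))
        assert offs.offsets[1] == pytest.approx(12.0)

    def test_region_outside_image_rejected(self):
        frames = [np.zeros((10, 10), dtype=np.uint8)] * 2
        with pytest.raises(ex.InputError):
            ex.compute_offsets(frames, (5, 5, 10, 10))

    def test_self_mode_overlap_warns_and_strict_raises(self):
        frames = [np.zeros((20, 20), dtype=np.uint8)] * 3
        damage = np.zeros((20, 20), dtype=bool)
        damage[5:15, 5:15] = True
        with pytest.warns(UserWarning, match="overlaps"):
            ex.compute_offsets(frames, (4, 4, 12, 12), mode="self",
                               damage_estimate=damage)
        with pytest.raises(ex.RegionOverlapError):
            ex.compute_offsets(frames, (4, 4, 12, 12), mode="self",
                               damage_estimate=damage, strict=True)

    def test_control_offsets_track_speckle_rise(self, small_noiseless_series):
        """On a noiseless phantom the control offsets equal the speckle
        drift, which grows linearly with time."""
        cfg = small_noiseless_series.config
        gray_c = [ex.to_saturation_channel(f) for f in small_noiseless_series.c_frames]
        region = ex.default_reference_region(gray_c[0].shape, skin_row=cfg.skin_row)
        offs = ex.compute_offsets(gray_c, region, mode="control")
        fit = stats.linregress(cfg.times, offs.offsets)
        assert fit.slope > 0
        assert fit.rvalue**2 > 0.9

    def test_corrected_undamaged_region_is_flat(self, small_noiseless_series):
        """After subtracting the control offsets, an undamaged tissue region
        of the injury frames no longer drifts (its raw mean rises with the
        speckle density)."""
        cfg = small_noiseless_series.config
        gray_t = [ex.to_saturation_channel(f) for f in small_noiseless_series.t_frames]
        gray_c = [ex.to_saturation_channel(f) for f in small_noiseless_series.c_frames]
        region = (30, 220, 180, 60)  # below the plateau halo, above the bottom band
        offs = ex.compute_offsets(gray_c, region, mode="control")
        x, y, w, h = region
        corrected = [
            ex.apply_correction(g, d)[y : y + h, x : x + w].mean()
            for g, d in zip(gray_t, offs.offsets)
        ]
        slope = stats.linregress(cfg.times, corrected).slope
        raw_slope = stats.linregress(
            cfg.times, [g[y : y + h, x : x + w].mean() for g in gray_t]
        ).slope
        assert raw_slope > 0
        assert abs(slope) < 0.25 * abs(raw_slope)

    def test_first_offset_must_be_zero(self):
        with pytest.raises(ex.InputError):
            ex.CorrectionOffsets(offsets=np.array([1.0, 0.0]), mode="self",
                                 region=(0, 0, 1, 1))


class TestApplyCorrection:
    def test_zero_offset_is_identity(self, rng):
        g = rng.integers(0, 256, size=(15, 15), dtype=np.uint8)
        assert np.array_equal(ex.apply_correction(g, 0.0), g)

    def test_exact_shift_restores_baseline(self):
        base = np.arange(100, dtype=np.uint8).reshape(10, 10)
        shifted = (base + 12).astype(np.uint8)
        assert np.array_equal(ex.apply_correction(shifted, 12.0), base)


class TestThresholding:
    def test_noiseless_phantom_masks_exact(self, small_noiseless_series):
        """Tri-level thresholds on a noiseless frame reproduce the drawn
        class regions exactly (artifact bands are at zone saturation)."""
        truth = small_noiseless_series.truth
        i = len(small_noiseless_series.t_frames) - 1
        gray = ex.to_saturation_channel(small_noiseless_series.t_frames[i])
        damage, zone, (t1, t2) = ex.binarize_three_class(gray)
        bands = truth.side_artifact_mask | truth.bottom_artifact_mask
        expected_zone = truth.zone_masks[i] | bands
        expected_damage = truth.damage_masks[i] | bands | truth.speckle_masks[i]
        assert np.array_equal(zone, expected_zone)
        assert np.array_equal(damage, expected_damage)

    def test_zone_subset_of_damage(self, rng):
        gray = rng.integers(0, 256, size=(30, 30), dtype=np.uint8)
        damage, zone, _ = ex.binarize_three_class(gray)
        assert not np.any(zone & ~damage)

    def test_matches_brute_force_search(self, rng):
        """Exhaustive threshold-pair oracle on small three-class samples."""
        for _ in range(5):
            gray = np.concatenate(
                [
                    rng.normal(50, 8, 40),
                    rng.normal(130, 8, 35),
                    rng.normal(200, 8, 25),
                ]
            )
            gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
            t1, t2 = ex.three_class_otsu_thresholds(gray)
            bt1, bt2, bvar = brute_force_three_class_otsu(gray)
            assert (t1, t2) == (bt1, bt2)

    def test_agrees_with_multiotsu_on_noisy_image(self, rng):
        gray = np.clip(
            np.rint(
                np.concatenate(
                    [
                        rng.normal(40, 6, 3000),
                        rng.normal(120, 6, 2000),
                        rng.normal(180, 6, 1000),
                    ]
                )
            ),
            0,
            255,
        ).astype(np.uint8).reshape(100, 60)
        t1, t2 = ex.three_class_otsu_thresholds(gray)
        m1, m2 = threshold_multiotsu(gray, classes=3)
        ours = np.digitize(gray, [t1 + 0.5, t2 + 0.5])
        ref = np.digitize(gray, [m1, m2])
        assert (ours == ref).mean() > 0.995

    def test_constant_image_rejected(self):
        with pytest.raises(ex.DegenerateImageError):
            ex.three_class_otsu_thresholds(np.full((10, 10), 7, dtype=np.uint8))


class TestMorphology:
    def test_empty_mask_stays_empty(self):
        m = np.zeros((20, 20), dtype=bool)
        assert not ex.morphological_clean(m).any()

    def test_isolated_pixel_removed(self):
        m = np.zeros((20, 20), dtype=bool)
        m[10, 10] = True
        assert not ex.morphological_clean(m, radius=2).any()

    def test_wide_band_preserved(self):
        m = np.zeros((40, 40), dtype=bool)
        m[15:25, :] = True
        assert np.array_equal(ex.morphological_clean(m), m)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_idempotent(self, seed):
        r = np.random.default_rng(seed)
        m = r.random((48, 48)) < 0.35
        once = ex.morphological_clean(m)
        assert np.array_equal(ex.morphological_clean(once), once)


class TestLargestComponent:
    def test_single_component_unchanged(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:5, 2:8] = True
        assert np.array_equal(ex.largest_component(m), m)

    def test_keeps_bigger_of_two(self):
        m = np.zeros((10, 20), dtype=bool)
        m[1:2, 0:10] = True   # size 10
        m[7:8, 15:18] = True  # size 3
        out = ex.largest_component(m)
        assert out[1, :10].all() and not out[7, 15:18].any()

    def test_tie_broken_by_raster_order(self):
        m = np.zeros((10, 10), dtype=bool)
        m[1, 1:4] = True
        m[8, 5:8] = True
        out = ex.largest_component(m)
        assert out[1, 1:4].all() and not out[8].any()

    def test_empty_stays_empty(self):
        assert not ex.largest_component(np.zeros((5, 5), dtype=bool)).any()

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(50):
            m = rng.random((32, 32)) < 0.35
            assert np.array_equal(ex.largest_component(m), bfs_largest_component(m))


class TestFillHoles:
    def test_solid_rectangle_unchanged(self):
        m = np.zeros((12, 12), dtype=bool)
        m[3:9, 3:9] = True
        assert np.array_equal(ex.fill_holes(m), m)

    def test_interior_hole_filled(self):
        m = np.zeros((12, 12), dtype=bool)
        m[3:9, 3:9] = True
        holed = m.copy()
        holed[5, 5] = False
        assert np.array_equal(ex.fill_holes(holed), m)

    def test_matches_complement_oracle(self, rng):
        for _ in range(30):
            m = rng.random((24, 24)) < 0.45
            assert np.array_equal(ex.fill_holes(m), fill_holes_by_complement(m))


class TestSegmentMiddleThird:
    def test_single_band_unchanged(self):
        m = np.zeros((520, 600), dtype=bool)
        m[140:161, :] = True
        assert np.array_equal(ex.segment_middle_third(m), m)

    def test_cut_line_midway_between_rectangles(self):
        """Zone rows 140-160 and bottom band rows 460-500 put the cut at
        row 310; only the bottom band is erased."""
        m = np.zeros((520, 600), dtype=bool)
        m[140:161, :] = True
        m[460:501, :] = True
        out = ex.segment_middle_third(m)
        assert out[140:161, :].all()
        assert not out[311:, :].any()

    def test_empty_middle_third_rejected(self):
        m = np.zeros((60, 90), dtype=bool)
        m[10:20, 0:5] = True  # only in the left third
        with pytest.raises(ex.SegmentationError):
            ex.segment_middle_third(m)

    def test_narrow_blob_not_mistaken_for_artifact(self):
        m = np.zeros((100, 90), dtype=bool)
        m[40:50, :] = True
        m[5, 45:48] = True  # small blob above the band
        out = ex.segment_middle_third(m)
        assert np.array_equal(out, m)

    @pytest.mark.parametrize("seed", range(20))
    def test_bottom_artifact_removed_on_phantoms(self, seed):
        """Single-frame chain on seeded phantoms never retains bottom-band
        pixels after the middle-third cut."""
        series = render_series(small_config(seed=100 + seed, n_frames=2))
        truth = series.truth
        gray = ex.to_saturation_channel(series.t_frames[-1])
        _, zone, _ = ex.binarize_three_class(gray)
        chain = ex.fill_holes(
            ex.largest_component(ex.morphological_clean(zone))
        )
        out = ex.segment_middle_third(chain)
        assert not np.any(out & truth.bottom_artifact_mask)


class TestCorrectEndpoints:
    def test_uniform_band_unchanged(self):
        m = np.zeros((60, 40), dtype=bool)
        m[20:30, :] = True
        assert np.array_equal(ex.correct_endpoints(m), m)

    def test_wide_end_column_clamped(self):
        m = np.zeros((60, 40), dtype=bool)
        m[20:30, 1:] = True            # interior width 10
        m[10:40, 0] = True             # end column width 30
        out = ex.correct_endpoints(m)
        col = np.flatnonzero(out[:, 0])
        assert len(col) == 10
        assert (col[0] + col[-1]) / 2 == pytest.approx(24.5, abs=1.0)
        assert np.array_equal(out[:, 1:], m[:, 1:])

    def test_too_few_columns_rejected(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:10, 3] = True
        with pytest.raises(ex.MeasurementError):
            ex.correct_endpoints(m)

    def test_reduces_end_width_error_on_phantom(self, small_noiseless_series):
        """With side cutting bands, endpoint correction shrinks the
        per-column width error against ground truth."""
        series = small_noiseless_series
        truth = series.truth
        i = len(series.t_frames) - 1
        gray = ex.to_saturation_channel(series.t_frames[i])
        _, zone, _ = ex.binarize_three_class(gray)
        before = ex.segment_middle_third(
            ex.fill_holes(ex.largest_component(ex.morphological_clean(zone)))
        )
        after = ex.correct_endpoints(before)
        true_w = truth.zone_masks[i].sum(axis=0)
        err_before = np.abs(before.sum(axis=0) - true_w).sum()
        err_after = np.abs(after.sum(axis=0) - true_w).sum()
        assert err_after < err_before


class TestFullChain:
    def test_clean_phantom_recovered_pixel_perfect(self, small_clean_series):
        """Noise-free, artifact-free series: Jaccard index 1 on every frame
        for both masks."""
        res = ex.extract_series(
            small_clean_series.t_frames,
            c_frames=small_clean_series.c_frames,
            skin_row=small_clean_series.config.skin_row,
        )
        truth = small_clean_series.truth
        for got, want in zip(res.zone_masks, truth.zone_masks):
            assert np.array_equal(got, want)
        for got, want in zip(res.damage_masks, truth.damage_masks):
            assert np.array_equal(got, want)

    def test_default_noise_zone_jaccard(self, default_run):
        """Default study conditions (full geometry, noise, speckle, cut
        bands): zone masks stay close to truth on every frame."""
        truth = default_run.phantom.truth
        for got, want in zip(default_run.extraction.zone_masks, truth.zone_masks):
            inter = np.logical_and(got, want).sum()
            union = np.logical_or(got, want).sum()
            assert inter / union >= 0.85

    def test_correction_barely_touches_halo_pixels(self, full_noiseless_series):
        """With matched speckle fields the control correction changes halo
        pixels by at most ~1 gray level on a noiseless default-geometry
        phantom (the bound scales with pixel area, so the full-size
        geometry is the reference condition)."""
        series = full_noiseless_series
        cfg = series.config
        gray_t = [ex.to_saturation_channel(f) for f in series.t_frames]
        gray_c = [ex.to_saturation_channel(f) for f in series.c_frames]
        region = ex.default_reference_region(gray_t[0].shape, skin_row=cfg.skin_row)
        offs = ex.compute_offsets(gray_c, region, mode="control")
        changes = []
        for g, d, dm in zip(gray_t, offs.offsets, series.truth.damage_masks):
            corrected = ex.apply_correction(g, d)
            diff = np.abs(corrected.astype(float) - g.astype(float))[dm]
            if diff.size:
                changes.append(diff.mean())
        assert max(changes) <= 1.5

    def test_masks_binary_and_shape_preserved(self, small_run):
        res = small_run.extraction
        shape = small_run.phantom.t_frames[0].shape[:2]
        for m in res.zone_masks + res.damage_masks:
            assert m.shape == shape and m.dtype == bool

    def test_control_mode_requires_c_series(self, small_clean_series):
        with pytest.raises(ex.InputError):
            ex.extract_series(small_clean_series.t_frames, mode="control")
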