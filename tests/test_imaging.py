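"""Per-slice imaging operations: loading, filtering, segmentation, splitting
and pixel classification."""

import dataclasses

import numpy as np
import pytest
import tifffile
from PIL import Image

from triquant import synthgen
from triquant.errors import ImageFormatError, NoTissueError
from triquant.imaging import (
    GrayImage,
    ImagingConfig,
    SliceImage,
    TissueMask,
    apply_blue_filter,
    classify_infarct,
    detect_blue_area,
    find_midline,
    load_slice_image,
    measure_slice,
    segment_tissue,
    split_hemispheres,
    to_grayscale,
)


def _img(pixels):
    return SliceImage(np.asarray(pixels, dtype=np.uint8), slice_index=1)


def _solid(color, shape=(64, 64)):
    arr = np.empty((*shape, 3), dtype=np.uint8)
    arr[:] = color
    return arr


class TestLoadSliceImage:
    def test_png_identity_decode(self, tmp_path):
        path = tmp_path / "b1_s1.png"
        Image.fromarray(_solid((255, 255, 255))).save(path)
        img = load_slice_image(path, 1)
        assert img.pixels.shape == (64, 64, 3)
        assert (img.pixels == 255).all()
        assert img.slice_index == 1

    def test_16bit_tiff_rescaled_by_integer_division(self, tmp_path):
        path = tmp_path / "b1_s1.tiff"
        tifffile.imwrite(path, np.full((32, 32), 32896, dtype=np.uint16))
        img = load_slice_image(path, 2)
        assert (img.pixels == 32896 // 257).all()

    def test_rgba_transparent_border_composited_onto_white(self, tmp_path):
        rgba = np.zeros((32, 32, 4), dtype=np.uint8)
        rgba[8:24, 8:24] = (200, 10, 10, 255)  # opaque core, transparent rim
        path = tmp_path / "b1_s3.png"
        Image.fromarray(rgba, mode="RGBA").save(path)
        img = load_slice_image(path, 3)
        assert (img.pixels[0, 0] == 255).all()
        assert tuple(img.pixels[16, 16]) == (200, 10, 10)

    def test_semitransparent_pixel_matches_manual_compositing(self, tmp_path):
        rgba = np.zeros((16, 16, 4), dtype=np.uint8)
        rgba[:] = (100, 50, 200, 128)
        path = tmp_path / "b_s1.png"
        Image.fromarray(rgba, mode="RGBA").save(path)
        img = load_slice_image(path, 1)
        a = 128 / 255
        expected = tuple(round(c * a + 255 * (1 - a)) for c in (100, 50, 200))
        assert tuple(img.pixels[4, 4]) == expected

    def test_grayscale_promoted_to_rgb(self, tmp_path):
        path = tmp_path / "g_s1.png"
        Image.fromarray(np.full((20, 20), 77, dtype=np.uint8), mode="L").save(path)
        img = load_slice_image(path, 1)
        assert (img.pixels == 77).all()

    def test_missing_file_raises_ioerror_naming_path(self, tmp_path):
        with pytest.raises(IOError, match="nope_s1.png"):
            load_slice_image(tmp_path / "nope_s1.png", 1)

    def test_float_tiff_rejected(self, tmp_path):
        path = tmp_path / "f_s1.tiff"
        tifffile.imwrite(path, np.zeros((20, 20), dtype=np.float32))
        with pytest.raises(ImageFormatError):
            load_slice_image(path, 1)


class TestColorTransforms:
    @pytest.mark.parametrize(
        "color, expected",
        [((0, 0, 255), 1.0), ((255, 0, 0), 0.0), ((60, 60, 200), 200 / 255)],
    )
    def test_blue_filter_extracts_blue_channel(self, color, expected):
        out = apply_blue_filter(_img(_solid(color, (16, 16))))
        assert out.pixels[0, 0] == pytest.approx(expected)

    def test_blue_filter_clamps_mixed_output(self):
        out = apply_blue_filter(_img(_solid((200, 200, 200), (16, 16))), (1.0, 1.0, 0.0))
        assert out.pixels.max() == 1.0  # 400 clamped to 255

    @pytest.mark.parametrize("coeffs", [(0, 0, 3), (0, 0), (0, np.nan, 1)])
    def test_blue_filter_rejects_bad_coefficients(self, coeffs):
        with pytest.raises(ValueError):
            apply_blue_filter(_img(_solid((0, 0, 0), (16, 16))), coeffs)

    @pytest.mark.parametrize(
        "color, expected",
        [((255, 255, 255), 1.0), ((0, 0, 255), 0.114), ((255, 0, 0), 0.299)],
    )
    def test_luminance_weights(self, color, expected):
        out = to_grayscale(_img(_solid(color, (16, 16))))
        assert out.pixels[0, 0] == pytest.approx(expected)


class TestSegmentTissue:
    def test_solid_square_on_white(self):
        canvas = _solid((255, 255, 255))
        canvas[10:50, 10:50] = (190, 40, 40)
        mask = segment_tissue(_img(canvas))
        assert mask.area_px == 1600

    def test_all_white_raises_no_tissue(self):
        with pytest.raises(NoTissueError):
            segment_tissue(_img(_solid((255, 255, 255))))

    def test_small_speck_removed(self):
        canvas = _solid((255, 255, 255))
        canvas[10:50, 10:50] = (190, 40, 40)
        canvas[55, 55:58] = (190, 40, 40)  # 3-px speck
        mask = segment_tissue(_img(canvas), min_object_px=10)
        assert mask.area_px == 1600
        assert not mask.pixels[55, 55:58].any()

    def test_interior_holes_filled(self):
        canvas = _solid((255, 255, 255))
        canvas[10:50, 10:50] = (190, 40, 40)
        canvas[25, 25] = (255, 255, 255)
        mask = segment_tissue(_img(canvas))
        assert mask.area_px == 1600

    def test_black_background_mode(self):
        canvas = _solid((0, 0, 0))
        canvas[10:30, 10:30] = (200, 200, 200)
        mask = segment_tissue(_img(canvas), background="black")
        assert mask.area_px == 400


class TestSplitHemispheres:
    def test_symmetric_phantom_splits_equally(self, clean_symmetric_brain):
        images, _ = clean_symmetric_brain
        tissue = segment_tissue(images[0])
        left, right = split_hemispheres(tissue)
        assert left.area_px == right.area_px
        assert left.area_px + right.area_px == tissue.area_px

    def test_flipped_orientation_swaps_labels(self, injured_brain):
        images, _ = injured_brain
        tissue = segment_tissue(images[2])
        left, right = split_hemispheres(tissue)
        fleft, fright = split_hemispheres(tissue, orientation="flipped")
        assert (fleft.pixels == right.pixels).all()
        assert (fright.pixels == left.pixels).all()

    def test_swollen_hemisphere_area_ratio_recovered(self):
        params = synthgen.PhantomParams(swelling_factor=1.10, noise_sd=0.0, seed=5)
        images, _ = synthgen.generate_brain(params)
        tissue = segment_tissue(images[2])
        left, right = split_hemispheres(tissue)
        assert right.area_px / left.area_px == pytest.approx(1.10, rel=0.02)

    def test_horizontal_flip_with_flipped_orientation_is_involution(self, injured_brain):
        images, truth = injured_brain
        img = images[1]
        tissue = segment_tissue(img)
        m = truth.midline_col
        left, right = split_hemispheres(tissue, midline=m)
        mirrored = TissueMask(tissue.pixels[:, ::-1].copy())
        w = tissue.shape[1]
        mleft, mright = split_hemispheres(mirrored, orientation="flipped", midline=w - m)
        assert (mleft.area_px, mright.area_px) == (left.area_px, right.area_px)

    def test_auto_midline_close_to_true_junction(self, injured_brain):
        images, truth = injured_brain
        tissue = segment_tissue(images[3])
        assert abs(find_midline(tissue) - truth.midline_col) <= 2

    def test_midline_outside_image_rejected(self, clean_symmetric_brain):
        images, _ = clean_symmetric_brain
        tissue = segment_tissue(images[0])
        with pytest.raises(ValueError):
            split_hemispheres(tissue, midline=tissue.shape[1] + 5)


class TestClassifyInfarct:
    def test_uniform_tissue_flagged_infarct_free(self):
        gray = GrayImage(np.full((32, 32), 0.1))
        tissue = TissueMask(np.ones((32, 32), dtype=bool))
        res = classify_infarct(gray, tissue)
        assert res.area_px == 0
        assert "degenerate-histogram" in res.flags

    def test_otsu_separates_bimodal_tissue_exactly(self):
        px = np.full((32, 32), 0.1)
        px[:, 16:] = 0.9
        res = classify_infarct(GrayImage(px), TissueMask(np.ones((32, 32), dtype=bool)))
        assert res.area_px == 32 * 16
        assert (res.mask == (px >= 0.9)).all()

    def test_fixed_level_thresholds_by_comparison(self):
        px = np.full((16, 16), 0.2)
        px[:4] = 0.7
        res = classify_infarct(
            GrayImage(px), TissueMask(np.ones((16, 16), dtype=bool)), method="fixed", level=0.5
        )
        assert res.area_px == 4 * 16

    def test_fixed_requires_level(self):
        gray = GrayImage(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            classify_infarct(gray, TissueMask(np.ones((16, 16), dtype=bool)), method="fixed")

    def test_noise_only_tissue_flagged_low_contrast(self, rng):
        vals = np.clip(rng.normal(0.15, 0.02, (32, 32)), 0, 1)
        res = classify_infarct(GrayImage(vals), TissueMask(np.ones((32, 32), dtype=bool)))
        assert res.area_px == 0
        assert "low-contrast" in res.flags

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_otsu_matches_exhaustive_search(self, seed):
        """Implementation threshold == brute-force between-class-variance max."""
        rng = np.random.default_rng(seed)
        levels = rng.choice(np.linspace(0, 1, 64), size=20, replace=False)
        vals = rng.choice(levels, size=(24, 24))
        tissue = TissueMask(np.ones((24, 24), dtype=bool))
        res = classify_infarct(GrayImage(vals), tissue, min_contrast=0.0)

        flat = vals.ravel()
        best_t, best_var = None, -1.0
        for t in sorted(set(flat))[1:]:
            lo, hi = flat[flat < t], flat[flat >= t]
            w0, w1 = len(lo) / len(flat), len(hi) / len(flat)
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var + 1e-15:
                best_var, best_t = var, t
        assert res.threshold == pytest.approx(best_t)


class TestDetectBlueArea:
    def test_pure_blue_region_detected_exactly(self):
        canvas = _solid((190, 40, 40))
        canvas[20:30, 20:32] = (40, 40, 180)
        tissue = TissueMask(np.ones((64, 64), dtype=bool))
        mask = detect_blue_area(_img(canvas), tissue, blue_margin=0.1)
        assert mask.sum() == 120
        assert mask[20:30, 20:32].all()

    def test_white_and_red_tissue_has_no_blue(self):
        canvas = _solid((255, 255, 255))
        canvas[:32] = (255, 0, 0)
        tissue = TissueMask(np.ones((64, 64), dtype=bool))
        assert detect_blue_area(_img(canvas), tissue).sum() == 0

    @pytest.mark.parametrize("margin", [0.0, 1.0, -0.2])
    def test_margin_must_be_in_open_unit_interval(self, margin):
        tissue = TissueMask(np.ones((16, 16), dtype=bool))
        with pytest.raises(ValueError):
            detect_blue_area(_img(_solid((0, 0, 0), (16, 16))), tissue, blue_margin=margin)


class TestMeasureSlice:
    def test_clean_symmetric_slice_measures_zero_injury(self, clean_symmetric_brain):
        images, _ = clean_symmetric_brain
        m = measure_slice(images[0])
        assert m.infarct_area_px == 0
        assert m.blue_area_px == 0
        assert m.left_area_px == m.right_area_px

    def test_injured_slice_recovers_painted_areas_within_3pct(self, injured_brain):
        images, truth = injured_brain
        total_inf = total_blue = 0
        for img in images:
            m = measure_slice(img)
            total_inf += m.infarct_area_px
            total_blue += m.blue_area_px
        assert total_inf == pytest.approx(truth.measurement.infarct_total_px, rel=0.03)
        assert total_blue == pytest.approx(truth.measurement.blue_total_px, rel=0.03)

    def test_left_right_areas_conserve_tissue(self, injured_brain):
        images, _ = injured_brain
        for img in images:
            m = measure_slice(img)
            tissue = segment_tissue(img)
            assert m.left_area_px + m.right_area_px == tissue.area_px

    def test_eb_overlay_barely_changes_filtered_infarct(self):
        """Painting dye inside the infarct moves the filtered count < 1%."""
        base = dict(infarct_fraction=0.12, swelling_factor=1.05, seed=77)
        imgs0, _ = synthgen.generate_brain(synthgen.PhantomParams(eb_fraction=0.0, **base))
        imgs1, _ = synthgen.generate_brain(synthgen.PhantomParams(eb_fraction=0.8, **base))
        inf0 = sum(measure_slice(i).infarct_area_px for i in imgs0)
        inf1 = sum(measure_slice(i).infarct_area_px for i in imgs1)
        assert inf1 == pytest.approx(inf0, rel=0.01)

    def test_unfiltered_luminance_loses_dyed_infarct(self):
        """Without the blue filter, dye-covered infarct reads as viable."""
        params = synthgen.PhantomParams(
            infarct_fraction=0.12, swelling_factor=1.05, eb_fraction=0.8, seed=77
        )
        images, truth = synthgen.generate_brain(params)
        cfg = dataclasses.replace(ImagingConfig(), use_blue_filter=False)
        unfiltered = sum(measure_slice(i, cfg).infarct_area_px for i in images)
        assert unfiltered < 0.75 * truth.measurement.infarct_total_px

    def test_blue_area_monotone_in_eb_fraction(self):
        counts = []
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
            params = synthgen.PhantomParams(
                infarct_fraction=0.12, eb_fraction=frac, seed=9, noise_sd=0.0
            )
            images, _ = synthgen.generate_brain(params)
            counts.append(sum(measure_slice(i).blue_area_px for i in images))
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]

    def test_errors_carry_slice_context(self):
        blank = _img(_solid((255, 255, 255)))
        blank = SliceImage(blank.pixels, slice_index=4)
        with pytest.raises(NoTissueError, match="slice 4"):
            measure_slice(blank)
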