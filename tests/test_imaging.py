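"""Unit and property tests for the PIXI image-processing pipeline."""

from __future__ import annotations

import numpy as np
import pytest
import tifffile
from hypothesis import given
from hypothesis import strategies as st

from conftest import dense_gaussian_background, draw_disk, reference_pixi
from pixinorm.imaging import (
    PixiConfig,
    PixiValidationError,
    WellImage,
    correct_and_invert,
    crop_borders,
    estimate_background,
    load_well_image,
    parse_image_filename,
    pixi_process,
    process_directory,
    total_pixel_intensity,
)


def make_image(pixels: np.ndarray, well: str = "B04") -> WellImage:
    return WellImage(plate_id="P1", well_id=well, pixels=pixels)


class TestWellImageValidation:
    def test_rejects_out_of_range_pixels(self):
        with pytest.raises(PixiValidationError, match=r"\[0, 1\]"):
            make_image(np.full((32, 32), 2.0))

    def test_rejects_non_finite_pixels(self):
        bad = np.full((32, 32), 0.5)
        bad[3, 3] = np.nan
        with pytest.raises(PixiValidationError, match="non-finite"):
            make_image(bad)

    def test_rejects_tiny_frames(self):
        with pytest.raises(PixiValidationError, match="16x16"):
            make_image(np.full((8, 32), 0.5))

    @pytest.mark.parametrize("well", ["I01", "A13", "A1", "a01", "B00"])
    def test_rejects_bad_well_ids(self, well):
        with pytest.raises(PixiValidationError, match="96-well"):
            make_image(np.full((32, 32), 0.5), well=well)


class TestEstimateBackground:
    def test_constant_image_is_fixed_point(self):
        img = make_image(np.full((64, 64), 0.8))
        bg = estimate_background(img, sigma_px=7.0)
        assert bg.shape == (64, 64)
        np.testing.assert_allclose(bg, 0.8, atol=1e-12)

    def test_small_sigma_limit_is_identity(self):
        rng = np.random.default_rng(0)
        img = make_image(rng.uniform(0.2, 0.8, (32, 32)))
        np.testing.assert_allclose(
            estimate_background(img, sigma_px=1e-6), img.pixels, atol=1e-6
        )

    def test_single_dark_pixel_matches_dense_convolution(self):
        # 101x101 flat field 0.9 with one zero pixel; wide blur nearly
        # restores the flat level at the centre.
        img = np.full((101, 101), 0.9)
        img[50, 50] = 0.0
        bg = estimate_background(make_image(img), sigma_px=20.0)
        assert abs(bg[50, 50] - 0.9) < 1e-3
        oracle = dense_gaussian_background(img, 20.0)
        np.testing.assert_allclose(bg, oracle, atol=1e-10)

    def test_rejects_nonpositive_sigma(self):
        img = make_image(np.full((32, 32), 0.5))
        with pytest.raises(PixiValidationError, match="sigma"):
            estimate_background(img, sigma_px=0.0)


class TestCorrectAndInvert:
    def test_flat_image_gives_zero_signal(self):
        img = np.full((64, 64), 0.7)
        signal = correct_and_invert(img, estimate_background(img, 5.0))
        np.testing.assert_allclose(signal, 0.0, atol=1e-12)

    def test_disk_interior_signal_matches_contrast(self):
        # With sigma much larger than the disk, the background over the
        # disk stays near the flat level, so interior signal ~ depth.
        img = draw_disk((301, 301), (150, 150), radius=6, depth=0.4)
        bg = dense_gaussian_background(img, 60.0)
        signal = correct_and_invert(img, bg)
        interior = signal[148:153, 148:153]
        np.testing.assert_allclose(interior, 0.4, rtol=0.05)

    def test_bright_pixels_clip_to_zero(self):
        img = np.full((32, 32), 0.5)
        img[10, 10] = 0.9  # brighter than local background
        signal = correct_and_invert(img, estimate_background(img, 3.0))
        assert signal[10, 10] == 0.0

    def test_clip_disabled_keeps_signed_values(self):
        img = np.full((32, 32), 0.5)
        img[10, 10] = 0.9
        signal = correct_and_invert(
            img, estimate_background(img, 3.0), clip_negative=False
        )
        assert signal[10, 10] < 0.0

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(PixiValidationError, match=r"\(16, 16\).*\(32, 32\)"):
            correct_and_invert(np.zeros((32, 32)), np.zeros((16, 16)))


class TestCropBorders:
    @pytest.mark.parametrize(
        "shape,fraction,expected",
        [
            ((100, 100), 0.05, (90, 90)),
            ((100, 100), 0.0, (100, 100)),
            ((100, 100), 0.25, (50, 50)),
            ((101, 77), 0.10, (81, 63)),  # floor per side, odd dims
        ],
    )
    def test_cropped_shapes(self, shape, fraction, expected):
        assert crop_borders(np.zeros(shape), fraction).shape == expected

    def test_zero_fraction_is_identity(self):
        rng = np.random.default_rng(1)
        grid = rng.uniform(size=(40, 50))
        np.testing.assert_array_equal(crop_borders(grid, 0.0), grid)

    def test_rejects_half_or_more(self):
        with pytest.raises(PixiValidationError, match="empty"):
            crop_borders(np.zeros((100, 100)), 0.5)

    @given(
        h=st.integers(20, 200),
        w=st.integers(20, 200),
        f=st.floats(0.0, 0.45),
    )
    def test_crop_is_contiguous_central_subgrid(self, h, w, f):
        grid = np.arange(h * w, dtype=float).reshape(h, w)
        out = crop_borders(grid, f)
        dy, dx = int(np.floor(f * h)), int(np.floor(f * w))
        assert out.shape == (h - 2 * dy, w - 2 * dx)
        np.testing.assert_array_equal(out, grid[dy : h - dy, dx : w - dx])


class TestTotalPixelIntensity:
    def test_zero_grid_sums_to_zero(self):
        assert total_pixel_intensity(np.zeros((64, 64))) == 0.0

    def test_rejects_negative_values_unless_signed(self):
        grid = np.full((16, 16), -0.1)
        with pytest.raises(PixiValidationError, match="clip"):
            total_pixel_intensity(grid)
        assert total_pixel_intensity(grid, allow_signed=True) < 0

    def test_disjoint_disks_are_additive(self):
        # Disk separations exceed the truncated kernel support, so the
        # pipeline is exactly additive for isolated objects.
        sigma, crop = 4.0, 0.05
        shape = (160, 160)
        a = draw_disk(shape, (60, 60), 5, 0.3)
        b = draw_disk(shape, (110, 110), 7, 0.25)
        joint = np.minimum(a, b)
        t_a = reference_pixi(a, sigma, crop)
        t_b = reference_pixi(b, sigma, crop)
        t_joint = reference_pixi(joint, sigma, crop)
        assert abs(t_joint - (t_a + t_b)) < 1e-6

        img = WellImage("P1", "A01", joint)
        res = pixi_process(img, PixiConfig(background_sigma_px=sigma, crop_fraction=crop))
        assert res.total_pixel_intensity == pytest.approx(t_joint, rel=1e-10)

    def test_doubling_sparse_cell_count_doubles_intensity(self):
        # At <5% area coverage the inversion is near-linear in count.
        rng = np.random.default_rng(3)
        shape, sigma = (300, 300), 10.0

        def render(centers):
            img = np.full(shape, 0.9)
            yy, xx = np.indices(shape)
            for cy, cx in centers:
                img = np.minimum(
                    img,
                    np.where(
                        (yy - cy) ** 2 + (xx - cx) ** 2 <= 9, 0.55, 0.9
                    ),
                )
            return img

        centers: list[tuple[float, float]] = []
        while len(centers) < 40:  # rejection-sample non-overlapping positions
            cand = tuple(rng.uniform(40, 260, 2))
            if all(np.hypot(cand[0] - y, cand[1] - x) > 12 for y, x in centers):
                centers.append(cand)
        t1 = reference_pixi(render(centers[:20]), sigma, 0.05)
        t2 = reference_pixi(render(centers), sigma, 0.05)
        assert t2 == pytest.approx(2 * t1, rel=0.02)


class TestPixiProcess:
    def test_flat_field_scores_near_zero(self):
        img = make_image(np.full((128, 128), 0.6))
        res = pixi_process(img, PixiConfig(background_sigma_px=10.0))
        assert res.total_pixel_intensity < 1e-6 * img.pixels.size

    def test_processed_dimensions_follow_crop_rule(self):
        img = make_image(np.full((128, 100), 0.6))
        res = pixi_process(img, PixiConfig(background_sigma_px=5.0, crop_fraction=0.05))
        assert (res.processed_height_px, res.processed_width_px) == (116, 90)

    def test_matches_brute_force_reference_on_64px_images(self):
        rng = np.random.default_rng(5)
        for sigma in (3.0, 8.0):
            pixels = np.clip(
                0.8 - 0.3 * (rng.uniform(size=(64, 64)) > 0.9)
                + rng.normal(0, 0.01, (64, 64)),
                0, 1,
            )
            res = pixi_process(
                make_image(pixels),
                PixiConfig(background_sigma_px=sigma, crop_fraction=0.05),
            )
            expected = reference_pixi(pixels, sigma, 0.05)
            assert res.total_pixel_intensity == pytest.approx(expected, rel=1e-5)

    def test_adding_interior_object_never_decreases_intensity(self):
        rng = np.random.default_rng(11)
        cfg = PixiConfig(background_sigma_px=8.0, crop_fraction=0.05)
        base = np.full((160, 160), 0.85)
        yy, xx = np.indices(base.shape)
        centers = rng.uniform(30, 130, (6, 2))
        img = base.copy()
        prev = pixi_process(make_image(img), cfg).total_pixel_intensity
        for cy, cx in centers:
            img = np.minimum(
                img, np.where((yy - cy) ** 2 + (xx - cx) ** 2 <= 16, 0.5, 1.0)
            )
            total = pixi_process(make_image(img), cfg).total_pixel_intensity
            assert total > prev
            prev = total

    def test_translation_robustness_within_one_percent(self):
        cfg = PixiConfig(background_sigma_px=6.0, crop_fraction=0.05)
        centers = [(60, 60), (100, 95), (75, 120)]
        img = np.full((160, 160), 0.85)
        for c in centers:
            img = np.minimum(img, draw_disk((160, 160), c, 5, 0.35, background=0.85))
        shifted = np.full((160, 160), 0.85)
        for cy, cx in centers:
            shifted = np.minimum(
                shifted, draw_disk((160, 160), (cy + 2, cx - 1), 5, 0.35, background=0.85)
            )
        t0 = pixi_process(make_image(img), cfg).total_pixel_intensity
        t1 = pixi_process(make_image(shifted), cfg).total_pixel_intensity
        assert abs(t1 - t0) / t0 < 0.01


class TestFileIO:
    def test_filename_convention_roundtrip(self, tmp_path):
        raw = (np.full((32, 32), 0.5) * 65535).astype(np.uint16)
        path = tmp_path / "plateX_C07.tif"
        tifffile.imwrite(path, raw)
        img = load_well_image(path)
        assert (img.plate_id, img.well_id) == ("plateX", "C07")
        assert img.bit_depth_source == 16
        np.testing.assert_allclose(img.pixels, 0.5, atol=1e-4)

    def test_uint8_rescaled_by_full_scale(self, tmp_path):
        import imageio.v3 as iio

        raw = np.full((32, 32), 51, dtype=np.uint8)
        path = tmp_path / "p_A01.png"
        iio.imwrite(path, raw)
        img = load_well_image(path)
        assert img.bit_depth_source == 8
        np.testing.assert_allclose(img.pixels, 51 / 255.0)

    def test_unparseable_filename_raises(self):
        with pytest.raises(PixiValidationError, match="parse"):
            parse_image_filename("nounderscore.tif")

    def test_process_directory_collects_all_wells(self, tmp_path):
        rng = np.random.default_rng(2)
        for well in ("A01", "A02", "B01"):
            raw = (rng.uniform(0.4, 0.6, (64, 64)) * 65535).astype(np.uint16)
            tifffile.imwrite(tmp_path / f"P1_{well}.tif", raw)
        df = process_directory(tmp_path, PixiConfig(background_sigma_px=5.0))
        assert list(df["well_id"]) == ["A01", "A02", "B01"]
        assert (df["total_pixel_intensity"] >= 0).all()
        assert set(df["crop_fraction"]) == {0.05}
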