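"""Imaging chain: center-weighted median, binning, Butterworth blur, boll
mask, ratiometric image."""

import numpy as np
import pytest

from bollmark.images import (
    BollMask,
    ColorImage,
    ImagingConfig,
    MonoImage,
    bin2x2,
    butterworth_lowpass,
    center_weighted_median,
    make_boll_mask,
    process_color_image,
    ratiometric_image,
)

from conftest import disk_image


def color(arr, **kw):
    return ColorImage(np.asarray(arr, dtype=float), **kw)


class TestCenterWeightedMedian:
    def test_constant_image_unchanged(self):
        img = color(np.full((5, 5, 3), 7.0))
        out = center_weighted_median(img, 3, 3)
        assert np.array_equal(out.pixels, img.pixels)

    def test_center_weight_multiset(self):
        # center 100 among 8 zero neighbors, weight 3: median of
        # {0 x8, 100 x3} over 11 elements is 0
        arr = np.zeros((3, 3, 3))
        arr[1, 1, :] = 100.0
        out = center_weighted_median(color(arr), 3, 3)
        assert out.pixels[1, 1, 0] == 0.0

    def test_weight_one_equals_plain_median(self, rng):
        arr = rng.integers(0, 4000, (5, 5, 3)).astype(float)
        out = center_weighted_median(color(arr), 3, 1)
        # brute-force oracle: sorted-multiset median per pixel, edge padded
        pad = np.pad(arr, ((1, 1), (1, 1), (0, 0)), mode="edge")
        for i in range(5):
            for j in range(5):
                for c in range(3):
                    expected = np.median(np.sort(pad[i : i + 3, j : j + 3, c].ravel()))
                    assert out.pixels[i, j, c] == expected

    @pytest.mark.parametrize("window", [2, 1, 4])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            center_weighted_median(color(np.zeros((4, 4, 3))), window, 1)


class TestBinning:
    def test_constant_blocks(self):
        out = bin2x2(color(np.full((4, 4, 3), 100.0)))
        assert out.pixels.shape == (2, 2, 3)
        assert np.all(out.pixels == 100.0)

    def test_block_means_oracle(self, rng):
        arr = rng.uniform(0, 4000, (4, 4, 3))
        out = bin2x2(color(arr))
        for i in range(2):
            for j in range(2):
                block = arr[2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                assert np.allclose(out.pixels[i, j], block.mean(axis=(0, 1)))

    def test_native_frame_reduces_to_published_size(self):
        img = color(np.zeros((3016, 2008, 3)), resolution_px_per_mm=36.0)
        out = bin2x2(img)
        assert out.shape == (1508, 1004)
        assert out.resolution_px_per_mm == 18.0

    def test_odd_dimension_dropped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = bin2x2(color(np.zeros((5, 6, 3))))
        assert out.shape == (2, 3)
        assert any("dropped" in r.message for r in caplog.records)


class TestButterworth:
    def test_dc_gain_unity(self):
        img = MonoImage(np.full((32, 32), 42.0))
        out = butterworth_lowpass(img)
        assert np.allclose(out.pixels, 42.0, atol=1e-9)

    def test_sinusoid_at_cutoff_attenuated_by_sqrt2(self):
        # cutoff wavelength 10 px -> f_c = 0.1 cycles/px, exactly on the
        # FFT grid of a 100-px-wide image
        x = np.arange(100)
        img = MonoImage(np.tile(np.sin(2 * np.pi * 0.1 * x), (64, 1)) + 5.0)
        out = butterworth_lowpass(img, order=2, cutoff_px=10)
        amp_in = (img.pixels.max() - img.pixels.min()) / 2
        amp_out = (out.pixels.max() - out.pixels.min()) / 2
        assert amp_out / amp_in == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        assert out.pixels.mean() == pytest.approx(img.pixels.mean(), rel=1e-6)

    def test_lowpass_removes_noise_energy(self, rng):
        img = MonoImage(rng.normal(0, 1, (64, 64)))
        out = butterworth_lowpass(img)
        assert out.pixels.var() < img.pixels.var()

    def test_nonfinite_input_rejected(self):
        arr = np.zeros((8, 8))
        with pytest.raises(ValueError):
            MonoImage(arr * np.nan)


class TestBollMask:
    def test_bright_disk_recovered_within_boundary_tolerance(self):
        img = MonoImage(disk_image(30, inside=1000.0, outside=10.0))
        mask = make_boll_mask(img, 100.0)
        rows = np.arange(128)[:, None]
        cols = np.arange(128)[None, :]
        d = np.sqrt((rows - 64) ** 2 + (cols - 64) ** 2)
        # away from the 1-px boundary band the mask must match the disk
        interior = d <= 29
        exterior = d >= 31
        assert np.all(mask.pixels[interior] == 1)
        assert np.all(mask.pixels[exterior] == 0)

    def test_all_background_gives_empty_mask(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            mask = make_boll_mask(MonoImage(np.zeros((16, 16))), 10.0)
        assert mask.pixels.sum() == 0
        assert len(caplog.records) >= 1

    def test_zero_threshold_on_positive_image_is_all_ones(self):
        mask = make_boll_mask(MonoImage(np.full((16, 16), 3.0)), 0.0)
        assert np.all(mask.pixels == 1)

    def test_specks_removed(self):
        arr = disk_image(30, inside=1000.0, outside=0.0)
        arr[2:4, 2:4] = 1000.0  # 4-px speck far from the boll
        mask = make_boll_mask(MonoImage(arr), 100.0, min_speck_px=100)
        assert mask.pixels[2, 2] == 0
        assert mask.pixels[64, 64] == 1


class TestRatiometric:
    def test_equal_channels_full_mask_is_one(self):
        g = MonoImage(np.full((8, 8), 500.0))
        mask = BollMask(np.ones((8, 8), np.uint8))
        out = ratiometric_image(g, g, mask)
        assert np.allclose(out.pixels, 1.0)

    def test_zero_mask_zeroes_everything(self, rng):
        g = MonoImage(rng.uniform(1, 100, (8, 8)))
        r = MonoImage(rng.uniform(1, 100, (8, 8)))
        out = ratiometric_image(g, r, BollMask(np.zeros((8, 8), np.uint8)))
        assert np.all(out.pixels == 0)

    def test_elementwise_division_oracle(self):
        r = np.full((8, 8), 100.0)
        g = np.full((8, 8), 100.0)
        g[:, :4] = 200.0
        mask = BollMask(np.ones((8, 8), np.uint8))
        out = ratiometric_image(MonoImage(g), MonoImage(r), mask)
        assert np.allclose(out.pixels[:, :4], 2.0)
        assert np.allclose(out.pixels[:, 4:], 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ratiometric_image(
                MonoImage(np.ones((4, 4))),
                MonoImage(np.ones((5, 5))),
                BollMask(np.ones((4, 4), np.uint8)),
            )

    def test_ratio_invariant_under_joint_rescaling(self, rng):
        g = MonoImage(rng.uniform(100, 1000, (8, 8)))
        r = MonoImage(rng.uniform(100, 1000, (8, 8)))
        mask = BollMask(np.ones((8, 8), np.uint8))
        a = ratiometric_image(g, r, mask)
        b = ratiometric_image(
            MonoImage(3.7 * g.pixels), MonoImage(3.7 * r.pixels), mask
        )
        assert np.allclose(a.pixels, b.pixels)

    def test_mask_multiplication_idempotent(self, rng):
        g = MonoImage(rng.uniform(100, 1000, (8, 8)))
        r = MonoImage(rng.uniform(100, 1000, (8, 8)))
        m = (rng.uniform(size=(8, 8)) > 0.4).astype(np.uint8)
        out = ratiometric_image(g, r, BollMask(m))
        assert np.array_equal(out.pixels * m, out.pixels)


class TestFullChain:
    def test_synthetic_scene_background_is_zero(self):
        from bollmark.synthetic import generate_boll_image, random_scene

        img, _ = generate_boll_image(random_scene(seed=7))
        ratio = process_color_image(img)
        assert np.all(ratio.pixels[ratio.mask.pixels == 0] == 0)
        assert ratio.mask.pixels.any()
        assert np.all(np.isfinite(ratio.pixels))

    def test_mask_threshold_insensitive_over_wide_range(self):
        # black backdrop: mask area changes little between 5% and 50%
        from bollmark.synthetic import generate_boll_image, random_scene

        img, _ = generate_boll_image(random_scene(seed=7))
        areas = []
        for frac in (0.05, 0.2, 0.5):
            cfg = ImagingConfig(mask_threshold=None)
            from bollmark.images import (
                bin2x2 as _bin,
                butterworth_lowpass as _bw,
                center_weighted_median as _med,
                make_boll_mask as _mask,
            )

            binned = _bin(_med(img))
            blur = _bw(binned.channel("red"))
            areas.append(_mask(blur, frac * blur.pixels.max()).pixels.sum())
        assert max(areas) / min(areas) < 1.10

    def test_mask_channel_configurable(self):
        from bollmark.synthetic import generate_boll_image, random_scene

        img, _ = generate_boll_image(random_scene(seed=7))
        red = process_color_image(img, ImagingConfig(mask_channel="red"))
        green = process_color_image(img, ImagingConfig(mask_channel="green"))
        assert red.mask.pixels.any() and green.mask.pixels.any()


class TestColorImageValidation:
    def test_rejects_values_beyond_bit_depth(self):
        with pytest.raises(ValueError):
            ColorImage(np.full((4, 4, 3), 5000.0), bit_depth=12)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            ColorImage(np.full((4, 4, 3), -1.0))

    def test_rejects_tiny_images(self):
        with pytest.raises(ValueError):
            ColorImage(np.zeros((1, 5, 3)))
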