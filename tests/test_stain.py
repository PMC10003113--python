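"""Stain generator and color-index quantification."""

import numpy as np
import pytest
from scipy import stats as sps

from photoskin import stain
from photoskin.synth import gen_stain_image
from photoskin.synth.stain import DEFAULT_STAIN_BAND


class TestGenerator:
    def test_deterministic(self):
        a, _ = gen_stain_image(f=0.3, seed=8)
        b, _ = gen_stain_image(f=0.3, seed=8)
        assert np.array_equal(a.pixels, b.pixels)

    def test_truth_fraction_exact(self):
        _, truth = gen_stain_image(f=0.37, seed=1)
        assert truth.stained_mask[truth.roi].mean() == pytest.approx(truth.stained_fraction, abs=1e-12)
        assert truth.stained_fraction == pytest.approx(0.37, abs=1.0 / truth.roi.sum())

    def test_zero_fraction_no_stain_pixels(self):
        img, _ = gen_stain_image(f=0.0, seed=2)
        assert not stain.select_stain_pixels(img.pixels).any()

    def test_full_fraction_covers_roi(self):
        img, truth = gen_stain_image(f=1.0, seed=2)
        mask = stain.select_stain_pixels(img.pixels)
        assert (mask & truth.roi).sum() == truth.roi.sum()

    def test_invalid_fraction_and_empty_roi(self):
        with pytest.raises(ValueError):
            gen_stain_image(f=1.5, seed=0)
        with pytest.raises(ValueError, match="empty ROI"):
            gen_stain_image(f=0.5, seed=0, roi=np.zeros((256, 256), dtype=bool))


class TestSelection:
    def test_pure_stain_image_full_mask(self):
        from skimage import color as skcolor

        hsv = np.zeros((8, 8, 3))
        hsv[..., 0] = 0.89
        hsv[..., 1] = 0.7
        hsv[..., 2] = 0.8
        rgb = (skcolor.hsv2rgb(hsv) * 255).astype(np.uint8)
        assert stain.select_stain_pixels(rgb).all()

    def test_empty_band_rejected(self):
        img, _ = gen_stain_image(f=0.2, seed=0)
        with pytest.raises(ValueError):
            stain.select_stain_pixels(img.pixels, hue_band=(0.5, 0.5))

    def test_wraparound_band(self):
        from skimage import color as skcolor

        hsv = np.zeros((4, 4, 3))
        hsv[..., 0] = 0.01  # red, just past the wrap
        hsv[..., 1] = 0.9
        hsv[..., 2] = 0.9
        rgb = (skcolor.hsv2rgb(hsv) * 255).astype(np.uint8)
        assert stain.select_stain_pixels(rgb, hue_band=(0.95, 0.05)).all()


class TestHistogram:
    def test_counts_conserve_mask_size(self, rng):
        img, truth = gen_stain_image(f=0.4, seed=5)
        mask = rng.random(truth.roi.shape) < 0.3
        counts = stain.color_histogram(img.pixels, mask)
        assert counts.sum() == mask.sum()

    def test_empty_mask_all_zero(self):
        img, _ = gen_stain_image(f=0.4, seed=5)
        counts = stain.color_histogram(img.pixels, np.zeros(img.pixels.shape[:2], dtype=bool))
        assert (counts == 0).all()

    def test_argmax_bin_matches_generator_hue(self):
        img, truth = gen_stain_image(f=0.5, seed=3)
        mask = stain.select_stain_pixels(img.pixels) & truth.roi
        counts = stain.color_histogram(img.pixels, mask)
        center = (np.argmax(counts) + 0.5) / len(counts)
        lo, hi = truth.hue_band
        assert lo <= center <= hi


class TestColorIndex:
    def test_all_pixels_in_peak_gives_one(self):
        counts = np.zeros(255, dtype=int)
        counts[100] = 500
        res = stain.color_index(counts, np.array([100]), roi_area_px=500)
        assert res.color_index == 1.0

    def test_no_pixels_in_peak_gives_zero(self):
        res = stain.color_index(np.zeros(255, dtype=int), np.array([10, 11]), roi_area_px=100)
        assert res.color_index == 0.0

    def test_zero_roi_area_is_error(self):
        with pytest.raises(ValueError):
            stain.color_index(np.zeros(255, dtype=int), np.array([0]), roi_area_px=0)

    def test_recovers_generated_fraction(self):
        img, truth = gen_stain_image(f=0.25, seed=6)
        res = stain.quantify_section(img, truth.roi)
        assert res.color_index == pytest.approx(0.25, abs=0.02)

    def test_brightness_rescaling_invariance(self):
        """Multiplying all channels by 0.8 preserves hue, hence the index."""
        img, truth = gen_stain_image(f=0.3, seed=7)
        res1 = stain.quantify_section(img.pixels, truth.roi)
        dimmed = (img.pixels.astype(float) * 0.8).round().astype(np.uint8)
        res2 = stain.quantify_section(dimmed, truth.roi)
        assert res2.color_index == pytest.approx(res1.color_index, abs=1.0 / 255)


class TestNormalization:
    def test_identity_and_zero(self):
        assert stain.normalize_to_control(0.4, 0.4) == pytest.approx(100.0)
        assert stain.normalize_to_control(0.0, 0.4) == 0.0

    def test_zero_control_is_error(self):
        with pytest.raises(ValueError):
            stain.normalize_to_control(0.2, 0.0)

    def test_treated_vs_stressed_control_ratio(self):
        """f = 0.07 treated vs f = 0.50 control reads ~14% of control."""
        treated_img, treated_truth = gen_stain_image(f=0.07, seed=11)
        control_img, control_truth = gen_stain_image(f=0.50, seed=12)
        control = stain.quantify_section(control_img, control_truth.roi)
        res = stain.quantify_section(
            treated_img, treated_truth.roi, control_index=control.color_index
        )
        assert res.percent_of_control == pytest.approx(14.0, abs=2.0)


def test_recovered_index_affine_in_fraction():
    """Over f in {0.05..0.5} the recovered index is linear with slope 1."""
    fractions = np.arange(0.05, 0.51, 0.05)
    recovered = []
    for i, f in enumerate(fractions):
        img, truth = gen_stain_image(f=float(f), seed=100 + i)
        recovered.append(stain.quantify_section(img, truth.roi).color_index)
    fit = sps.linregress(fractions, recovered)
    assert fit.slope == pytest.approx(1.0, abs=0.05)
    assert abs(fit.intercept) < 0.02
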