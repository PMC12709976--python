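"""Otsu thresholding, powder segmentation, FI and AG."""

import numpy as np
import pytest

from powderflow import (
    ContractError,
    DegenerateHistogramError,
    GrayImage,
    Histogram,
    RegionMask,
    agglomeration_ratio,
    analyze_image,
    flow_index,
    otsu_threshold,
    segment_powder,
)

from conftest import make_three_level_image


def otsu_brute_force(counts):
    """Independent oracle: exhaustive search of all 255 cuts for the maximal
    between-class variance, lowest cut winning ties."""
    counts = np.asarray(counts, dtype=np.float64)
    bins = np.arange(256)
    best_t, best_v = None, -1.0
    for t in range(255):
        w1 = counts[: t + 1].sum()
        w2 = counts[t + 1 :].sum()
        if w1 == 0 or w2 == 0:
            continue
        mu1 = (counts[: t + 1] * bins[: t + 1]).sum() / w1
        mu2 = (counts[t + 1 :] * bins[t + 1 :]).sum() / w2
        v = w1 * w2 * (mu1 - mu2) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def hist_from_counts(pairs):
    counts = np.zeros(256, dtype=np.int64)
    for level, n in pairs:
        counts[level] = n
    return Histogram(counts)


class TestOtsu:
    def test_two_spike_histogram_splits_the_modes(self):
        h = hist_from_counts([(50, 50), (200, 50)])
        t = otsu_threshold(h)
        assert 50 <= t < 200
        assert t == otsu_brute_force(h.counts)

    def test_matches_brute_force_on_random_histograms(self, rng):
        for _ in range(120):
            counts = rng.integers(0, 25, size=256)
            h = Histogram(counts.astype(np.int64))
            if h.n_occupied < 2:
                continue
            assert otsu_threshold(h) == otsu_brute_force(counts)

    def test_matches_skimage_on_random_histograms(self, rng):
        """Cross-check against an independent library implementation."""
        from skimage.filters import threshold_otsu

        for _ in range(30):
            counts = rng.integers(0, 25, size=256).astype(np.int64)
            h = Histogram(counts)
            t_ref = threshold_otsu(hist=(counts, np.arange(256)))
            assert otsu_threshold(h) == int(t_ref)

    def test_single_bin_is_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(hist_from_counts([(100, 500)]))

    def test_fewer_than_two_pixels_is_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(hist_from_counts([(5, 1)]))


class TestSegmentPowder:
    def _two_level(self, dark_frac=0.3, dark=60, bright=230, n=100):
        px = np.full((n, n), bright, dtype=np.uint8)
        px[: int(n * dark_frac)] = dark
        return GrayImage(px)

    def test_backlit_dark_class_is_powder(self):
        img = self._two_level()
        seg = segment_powder(img, RegionMask.full(100, 100), "backlight")
        np.testing.assert_array_equal(seg.mask.members, img.pixels == 60)
        assert 60 <= seg.threshold < 230

    def test_uniform_roi_gives_empty_mask_with_flag(self):
        img = GrayImage(np.full((50, 50), 230, dtype=np.uint8))
        seg = segment_powder(img, RegionMask.full(50, 50), "backlight")
        assert seg.degenerate
        assert seg.mask.count == 0
        assert seg.threshold is None

    def test_frontlit_bright_class_is_powder(self):
        img = GrayImage(255 - self._two_level().pixels)
        seg = segment_powder(img, RegionMask.full(100, 100), "frontlight")
        np.testing.assert_array_equal(seg.mask.members, img.pixels == 195)

    def test_polarity_inversion_symmetry(self):
        """Inverting intensities and flipping the polarity yields the same mask."""
        img = self._two_level(dark_frac=0.2)
        inv = GrayImage(255 - img.pixels)
        roi = RegionMask.full(100, 100)
        a = segment_powder(img, roi, "backlight")
        b = segment_powder(inv, roi, "frontlight")
        np.testing.assert_array_equal(a.mask.members, b.mask.members)

    def test_tiny_components_are_suppressed(self):
        px = np.full((50, 50), 230, dtype=np.uint8)
        px[0:10, 0:10] = 60  # 100-px blob, kept
        px[30, 30] = 60  # isolated speck, removed
        seg = segment_powder(GrayImage(px), RegionMask.full(50, 50), "backlight")
        assert seg.mask.count == 100

    def test_empty_roi_raises(self):
        img = self._two_level()
        with pytest.raises(ContractError):
            segment_powder(img, RegionMask.empty(100, 100), "backlight")

    def test_auto_polarity_detects_bright_border_as_backlight(self):
        px = np.full((100, 100), 230, dtype=np.uint8)
        px[40:60, 40:60] = 60  # central dark pattern
        seg = segment_powder(GrayImage(px), RegionMask.full(100, 100), "auto")
        assert seg.polarity == "backlight"
        px_inv = 255 - px
        seg = segment_powder(GrayImage(px_inv), RegionMask.full(100, 100), "auto")
        assert seg.polarity == "frontlight"


class TestFlowIndex:
    def test_empty_powder_is_zero(self):
        assert flow_index(RegionMask.empty(10, 10), RegionMask.full(10, 10)) == 0.0

    def test_powder_equals_roi_is_hundred(self):
        assert flow_index(RegionMask.full(10, 10), RegionMask.full(10, 10)) == 100.0

    def test_direct_ratio(self):
        m = np.zeros((100, 100), dtype=bool)
        m.ravel()[:2835] = True
        assert flow_index(RegionMask(m), RegionMask.full(100, 100)) == pytest.approx(28.35)

    def test_contract_errors(self):
        with pytest.raises(ContractError):
            flow_index(RegionMask.empty(10, 10), RegionMask.empty(10, 10))
        with pytest.raises(ContractError):
            flow_index(RegionMask.full(10, 10), RegionMask.empty(10, 10))

    def test_adding_powder_pixels_never_decreases_fi(self, rng):
        roi = RegionMask.full(20, 20)
        m = rng.random((20, 20)) < 0.3
        fi1 = flow_index(RegionMask(m), roi)
        grown = m.copy()
        grown[0, 0] = True
        assert flow_index(RegionMask(grown), roi) >= fi1


class TestAgglomerationRatio:
    def test_single_intensity_powder_flags_unimodal(self):
        img = GrayImage(np.full((10, 10), 120, dtype=np.uint8))
        res = agglomeration_ratio(img, RegionMask.full(10, 10))
        assert res.ag == 0.0
        assert not res.bimodal

    def test_two_mode_powder_gives_dark_fraction(self):
        px = np.full((10, 10), 160, dtype=np.uint8)
        px.ravel()[:40] = 60  # 40% agglomerate
        res = agglomeration_ratio(GrayImage(px), RegionMask.full(10, 10))
        assert res.bimodal
        assert res.ag == pytest.approx(0.40)

    def test_dark_plus_bright_fractions_conserve(self):
        px = np.full((10, 10), 160, dtype=np.uint8)
        px.ravel()[:40] = 60
        img = GrayImage(px)
        mask = RegionMask.full(10, 10)
        dark = agglomeration_ratio(img, mask, dense_is_dark=True)
        bright = agglomeration_ratio(img, mask, dense_is_dark=False)
        assert dark.ag + bright.ag == pytest.approx(1.0)

    def test_empty_powder_mask_raises(self):
        img = GrayImage(np.full((10, 10), 120, dtype=np.uint8))
        with pytest.raises(ContractError):
            agglomeration_ratio(img, RegionMask.empty(10, 10))


class TestAnalyzeImage:
    def test_uniform_bright_image(self):
        img = GrayImage(np.full((50, 50), 230, dtype=np.uint8))
        m = analyze_image(img, polarity="backlight")
        assert m.fi_percent == 0.0
        assert m.ag_ratio == 0.0
        assert not m.bimodality_flag
        assert m.degenerate_roi

    def test_two_level_backlit_fixture(self):
        img = make_three_level_image(coverage=0.30, agglomerate_share=0.0)
        m = analyze_image(img, polarity="backlight")
        assert m.fi_percent == pytest.approx(30.0)
        assert m.ag_ratio == 0.0
        assert not m.bimodality_flag

    def test_three_level_backlit_fixture(self, three_level_image):
        m = analyze_image(three_level_image, polarity="backlight")
        assert m.fi_percent == pytest.approx(30.0)
        assert m.ag_ratio == pytest.approx(0.40)
        assert m.bimodality_flag
        assert m.powder_pixel_count == 3000
        assert m.roi_pixel_count == 10000
        assert m.fi_percent == pytest.approx(
            100.0 * m.powder_pixel_count / m.roi_pixel_count
        )

    def test_affine_intensity_remap_leaves_metrics_unchanged(self, three_level_image):
        """A strictly increasing, non-clipping affine remap must not move the
        powder mask, FI or AG (thresholding depends on rank order only)."""
        base = analyze_image(three_level_image, polarity="backlight")
        shifted = GrayImage((three_level_image.pixels + 20).astype(np.uint8))
        m = analyze_image(shifted, polarity="backlight")
        assert m.fi_percent == base.fi_percent
        assert m.ag_ratio == base.ag_ratio
        scaled = GrayImage((three_level_image.pixels // 2 * 2).astype(np.uint8))
        half = GrayImage((three_level_image.pixels // 2).astype(np.uint8))
        # doubling the halved image is affine with a = 2
        m2 = analyze_image(half, polarity="backlight")
        m3 = analyze_image(scaled, polarity="backlight")
        assert m2.fi_percent == m3.fi_percent
        assert m2.ag_ratio == m3.ag_ratio

    def test_translation_invariance_of_fi(self, three_level_image):
        rolled = GrayImage(np.roll(three_level_image.pixels, 17, axis=0))
        a = analyze_image(three_level_image, polarity="backlight")
        b = analyze_image(rolled, polarity="backlight")
        assert a.fi_percent == b.fi_percent

    def test_deterministic_for_fixed_inputs(self, three_level_image):
        assert analyze_image(three_level_image) == analyze_image(three_level_image)
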