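import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk

import pollenvia as pv
from pollenvia.channels import ChannelImage
from pollenvia.segment import SegmentationConfig, _isodata_from_histogram, channel_contrast


def isodata_fixed_points(hist):
    """Independent oracle: exhaustive scan of all 256 candidate thresholds
    for the integer fixed point T = round((mean_below + mean_above) / 2)."""
    hist = np.asarray(hist, dtype=float)
    values = np.arange(256)
    out = []
    for t in range(256):
        low, high = hist[: t + 1], hist[t + 1 :]
        if low.sum() == 0 or high.sum() == 0:
            continue
        mean_low = (low * values[: t + 1]).sum() / low.sum()
        mean_high = (high * values[t + 1 :]).sum() / high.sum()
        if int(np.floor((mean_low + mean_high) / 2.0 + 0.5)) == t:
            out.append(t)
    return out


def channel_from(arr):
    return ChannelImage(np.asarray(arr, dtype=np.uint8), "red", "test")


class TestAutoThreshold:
    def test_symmetric_two_valued_histogram_gives_midpoint(self):
        hist = np.zeros(256)
        hist[50] = hist[200] = 1000
        assert _isodata_from_histogram(hist) == 125

    def test_constant_image_raises(self):
        with pytest.raises(pv.DegenerateHistogramError):
            pv.auto_threshold(channel_from(np.full((10, 10), 128)))

    def test_matches_exhaustive_fixed_point_search(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            hist = rng.poisson(5.0, size=256).astype(float)
            hist[rng.integers(0, 128)] += rng.integers(100, 5000)
            hist[rng.integers(128, 256)] += rng.integers(100, 5000)
            fixed = isodata_fixed_points(hist)
            assert fixed, "oracle found no fixed point"
            assert _isodata_from_histogram(hist) == min(fixed)

    def test_separates_grains_from_background(self, small_scene, small_rgb):
        img, truth = small_scene
        red, _ = pv.select_counting_channels(small_rgb)
        t = pv.auto_threshold(red)
        from conftest import nonviable_mask, viable_mask

        grain = viable_mask(truth, img.shape[:2]) | nonviable_mask(truth, img.shape[:2])
        interior = ndi.binary_erosion(grain, iterations=2)
        assert np.mean(red.pixels[interior] <= t) > 0.99
        # background mode sits above the threshold
        assert np.median(red.pixels[~grain]) > t

    def test_otsu_available_and_in_range(self, small_rgb):
        red, _ = pv.select_counting_channels(small_rgb)
        assert 0 <= pv.auto_threshold(red, method="otsu") <= 255


class TestBinarize:
    def test_all_dark_all_foreground(self):
        assert pv.binarize(channel_from(np.zeros((5, 5))), 10).all()

    def test_all_bright_all_background(self):
        assert not pv.binarize(channel_from(np.full((5, 5), 255)), 10).any()

    def test_threshold_is_inclusive(self):
        ch = channel_from([[9, 10, 11]])
        assert pv.binarize(ch, 10).tolist() == [[True, True, False]]

    def test_disk_foreground_area_matches_truth(self):
        canvas = np.full((64, 64), 230, dtype=np.uint8)
        rr, cc = disk((32, 32), 12)
        canvas[rr, cc] = 60
        mask = pv.binarize(channel_from(canvas), 128)
        assert mask.sum() == len(rr)


class TestSolidify:
    def test_annulus_becomes_solid_disk(self):
        canvas = np.zeros((50, 50), bool)
        rr, cc = disk((25, 25), 15)
        canvas[rr, cc] = True
        rr, cc = disk((25, 25), 9)
        canvas[rr, cc] = False
        out = pv.solidify(canvas)
        assert ndi.binary_fill_holes(canvas).sum() == out.sum()
        # no interior holes remain
        assert np.array_equal(out, ndi.binary_fill_holes(out))

    def test_solid_disk_nearly_unchanged(self):
        canvas = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 18)
        canvas[rr, cc] = True
        out = pv.solidify(canvas)
        # closing may touch at most a perimeter's worth of pixels
        assert (out ^ canvas).sum() <= int(2 * np.pi * 18)

    def test_well_separated_components_stay_separate(self):
        canvas = np.zeros((60, 120), bool)
        for c in ((30, 30), (30, 90)):
            rr, cc = disk(c, 12)
            canvas[rr, cc] = True
        out = pv.solidify(canvas)
        assert ndi.label(out)[1] == 2


class TestWatershedSplit:
    def test_single_disk_one_label(self):
        canvas = np.zeros((80, 80), bool)
        rr, cc = disk((40, 40), 20)
        canvas[rr, cc] = True
        assert pv.watershed_split(canvas).n_labels == 1

    def test_fused_disk_pair_split_into_two_equal_halves(self):
        r = 20
        canvas = np.zeros((80, 120), bool)
        for c in ((40, 45), (40, 45 + int(1.5 * r))):
            rr, cc = disk(c, r)
            canvas[rr, cc] = True
        assert ndi.label(canvas)[1] == 1  # genuinely fused
        lm = pv.watershed_split(canvas)
        assert lm.n_labels == 2
        areas = np.bincount(lm.pixels.ravel())[1:]
        assert abs(areas[0] - areas[1]) / areas.max() <= 0.10

    def test_empty_mask_zero_labels(self):
        lm = pv.watershed_split(np.zeros((10, 10), bool))
        assert lm.n_labels == 0 and not lm.pixels.any()

    def test_split_never_merges_components(self):
        rng = np.random.default_rng(3)
        canvas = np.zeros((120, 120), bool)
        for _ in range(6):
            rr, cc = disk(rng.integers(15, 105, 2), int(rng.integers(5, 12)),
                          shape=canvas.shape)
            canvas[rr, cc] = True
        n_components = ndi.label(canvas, structure=np.ones((3, 3)))[1]
        assert pv.watershed_split(canvas).n_labels >= n_components

    def test_labels_subset_of_mask_and_disjoint(self):
        canvas = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 15)
        canvas[rr, cc] = True
        lm = pv.watershed_split(canvas)
        assert not (lm.pixels > 0)[~canvas].any()

    def test_watershed_disabled_keeps_fused_blob_single(self):
        r = 16
        canvas = np.zeros((70, 110), bool)
        for c in ((35, 35), (35, 35 + int(1.5 * r))):
            rr, cc = disk(c, r)
            canvas[rr, cc] = True
        cfg = SegmentationConfig(watershed_enabled=False)
        assert pv.watershed_split(canvas, cfg).n_labels == 1


class TestSegmentChannel:
    def test_recovers_exact_grain_count(self):
        spec = pv.SyntheticSceneSpec(
            image_size=(384, 512), n_viable=20, n_nonviable=0, n_artifacts=0, seed=5
        )
        img, truth = pv.generate_scene(spec)
        red, _ = pv.select_counting_channels(pv.RgbImage(img, "s"))
        assert pv.segment_channel(red).n_labels == truth.true_total == 20

    def test_noisy_blank_channel_yields_zero_labels(self):
        rng = np.random.default_rng(0)
        px = np.clip(rng.normal(235, 5, (256, 256)), 0, 255).astype(np.uint8)
        assert pv.segment_channel(ChannelImage(px, "green", "blank")).n_labels == 0

    def test_contrast_statistic_low_on_blank_high_on_scene(self, small_rgb):
        rng = np.random.default_rng(1)
        blank = ChannelImage(
            np.clip(rng.normal(235, 5, (128, 128)), 0, 255).astype(np.uint8), "green"
        )
        t = pv.auto_threshold(blank)
        assert channel_contrast(blank, t) < 25
        red, _ = pv.select_counting_channels(small_rgb)
        assert channel_contrast(red, pv.auto_threshold(red)) > 100


def test_config_validation():
    with pytest.raises(ValueError):
        SegmentationConfig(threshold_method="fixed")
    with pytest.raises(ValueError):
        SegmentationConfig(fixed_threshold=100)
    with pytest.raises(ValueError):
        SegmentationConfig(connectivity=6)
    with pytest.raises(ValueError):
        SegmentationConfig(morph_iterations=0)
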