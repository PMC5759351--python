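from math import pi

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.draw import disk

import pollenvia as pv
from pollenvia.channels import ChannelImage
from pollenvia.particles import GREEN_FILTER, RED_FILTER, kept_and_discarded_masks
from pollenvia.segment import LabeledMask, SegmentationConfig


def labeled_from(mask):
    from scipy import ndimage as ndi

    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    return LabeledMask(labels.astype(np.int32), n)


def record(area, circ, label=1):
    return pv.ParticleRecord(
        label=label, area=area, perimeter=1.0, circularity=circ, centroid=(0.0, 0.0)
    )


class TestMeasureParticles:
    def test_filled_square_area_and_centroid(self):
        mask = np.zeros((30, 30), bool)
        mask[5:15, 8:18] = True
        (p,) = pv.measure_particles(labeled_from(mask))
        assert p.area == 100
        assert p.centroid == (9.5, 12.5)

    def test_large_square_circularity_near_pi_over_4(self):
        mask = np.zeros((80, 80), bool)
        mask[10:60, 10:60] = True
        (p,) = pv.measure_particles(labeled_from(mask))
        assert p.circularity == pytest.approx(pi / 4, abs=0.1)

    def test_disk_circularity_close_to_one_and_capped(self):
        mask = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 20)
        mask[rr, cc] = True
        (p,) = pv.measure_particles(labeled_from(mask))
        assert 0.85 <= p.circularity <= 1.0

    def test_circularity_never_exceeds_one_for_small_particles(self):
        # tiny rasterized disks overshoot 4*pi*A/P^2 and must be capped
        mask = np.zeros((40, 40), bool)
        for c, r in (((10, 10), 2), ((10, 30), 3), ((30, 10), 4), ((30, 30), 1)):
            rr, cc = disk(c, r)
            mask[rr, cc] = True
        for p in pv.measure_particles(labeled_from(mask)):
            assert p.circularity <= 1.0

    def test_empty_mask_empty_list(self):
        assert pv.measure_particles(LabeledMask(np.zeros((5, 5), np.int32), 0)) == []

    def test_area_conservation(self, small_rgb):
        red, _ = pv.select_counting_channels(small_rgb)
        lm = pv.segment_channel(red)
        particles = pv.measure_particles(lm)
        assert sum(p.area for p in particles) == (lm.pixels > 0).sum()
        assert len(particles) == lm.n_labels


class TestApplyFilters:
    @pytest.mark.parametrize(
        "f,area,circ,expected",
        [
            (RED_FILTER, 59, 0.8, False),
            (RED_FILTER, 60, 0.8, True),
            (RED_FILTER, 800, 0.8, True),
            (RED_FILTER, 801, 0.8, False),
            (RED_FILTER, 400, 0.39, False),
            (RED_FILTER, 400, 0.40, True),
            (RED_FILTER, 400, 1.00, True),
            (GREEN_FILTER, 99, 0.9, False),
            (GREEN_FILTER, 100, 0.9, True),
            (GREEN_FILTER, 80, 0.9, False),  # balloon-artifact regime
            (GREEN_FILTER, 800, 0.9, True),
            (GREEN_FILTER, 801, 0.9, False),
            (GREEN_FILTER, 400, 0.39, False),
        ],
    )
    def test_inclusive_bounds(self, f, area, circ, expected):
        (out,) = pv.apply_filters([record(area, circ)], f)
        assert out.passed_filter is expected

    def test_order_preserved(self):
        records = [record(60 + i, 0.5, label=i + 1) for i in range(5)]
        out = pv.apply_filters(records, RED_FILTER)
        assert [p.label for p in out] == [1, 2, 3, 4, 5]

    @given(
        st.lists(
            st.tuples(st.floats(1, 2000), st.floats(0, 1)),
            max_size=40,
        ),
        st.floats(1, 500),
        st.floats(0, 300),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    def test_matches_brute_force_membership(self, specs, amin, awidth, c1, c2):
        f = pv.FilterConfig(amin, amin + awidth, min(c1, c2), max(c1, c2))
        records = [record(a, c, label=i + 1) for i, (a, c) in enumerate(specs)]
        out = pv.apply_filters(records, f)
        brute = [
            f.area_min <= a <= f.area_max and f.circ_min <= c <= f.circ_max
            for a, c in specs
        ]
        assert [p.passed_filter for p in out] == brute

    @given(
        st.lists(st.tuples(st.floats(1, 1200), st.floats(0, 1)), max_size=30),
        st.floats(0, 100),
        st.floats(0, 400),
        st.floats(0, 0.4),
    )
    def test_widening_bounds_is_monotone(self, specs, da, dA, dc):
        records = [record(a, c, label=i + 1) for i, (a, c) in enumerate(specs)]
        narrow = pv.FilterConfig(100, 800, 0.4, 1.0)
        wide = pv.FilterConfig(
            max(1e-6, 100 - da), 800 + dA, max(0.0, 0.4 - dc), 1.0
        )
        n_narrow = sum(p.passed_filter for p in pv.apply_filters(records, narrow))
        n_wide = sum(p.passed_filter for p in pv.apply_filters(records, wide))
        assert n_wide >= n_narrow

    def test_filter_config_validation(self):
        with pytest.raises(ValueError):
            pv.FilterConfig(0, 100)
        with pytest.raises(ValueError):
            pv.FilterConfig(100, 50)
        with pytest.raises(ValueError):
            pv.FilterConfig(60, 800, 0.5, 0.4)


class TestCountChannel:
    def test_specks_detected_but_not_counted(self):
        """3 sub-minimum specks + 5 valid disks: all detected, only the
        valid ones counted."""
        canvas = np.full((256, 256), 230, dtype=np.uint8)
        for c in ((30, 30), (30, 90), (30, 150)):  # specks, area ~ 13 px²
            rr, cc = disk(c, 2)
            canvas[rr, cc] = 60
        for c in ((120, 40), (120, 110), (120, 180), (200, 60), (200, 150)):
            rr, cc = disk(c, 10)  # valid grains, area ~ 314 px²
            canvas[rr, cc] = 60
        ch = ChannelImage(canvas, "red", "specks")
        cfg = SegmentationConfig(threshold_method="fixed", fixed_threshold=128)
        res = pv.count_channel(ch, cfg, RED_FILTER)
        assert res.n_detected == 8
        assert res.n_counted == 5

    def test_blank_channel_counts_zero(self):
        rng = np.random.default_rng(2)
        px = np.clip(rng.normal(235, 5, (128, 128)), 0, 255).astype(np.uint8)
        res = pv.count_channel(ChannelImage(px, "red", "blank"))
        assert res.n_counted == 0

    def test_green_counts_only_viable(self, small_rgb, small_scene):
        _, truth = small_scene
        _, green = pv.select_counting_channels(small_rgb)
        res = pv.count_channel(green)
        assert res.n_counted == truth.true_viable

    def test_red_counts_at_least_green(self, small_rgb):
        red, green = pv.select_counting_channels(small_rgb)
        assert pv.count_channel(red).n_counted >= pv.count_channel(green).n_counted


def test_kept_and_discarded_masks_partition_labels(small_rgb):
    red, _ = pv.select_counting_channels(small_rgb)
    lm = pv.segment_channel(red)
    particles = pv.apply_filters(pv.measure_particles(lm), RED_FILTER)
    kept, discarded = kept_and_discarded_masks(lm, particles)
    assert not ((kept > 0) & discarded).any()
    assert np.array_equal((kept > 0) | discarded, lm.pixels > 0)
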