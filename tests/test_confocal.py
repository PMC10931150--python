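"""Nuclear segmentation, colocalization coefficients, foci quantification."""

import math

import numpy as np
import pytest

from nucoloc import (
    ConfocalImagePair,
    FociStats,
    compare_foci_groups,
    manders_m1_m2,
    manders_overlap,
    pearson,
    quantify_foci,
    segment_nucleus,
)
from nucoloc.errors import ParameterError, SegmentationError, UndefinedResultError


def pair_from(a, b, px=1.0):
    return ConfocalImagePair(np.asarray(a, float), np.asarray(b, float), pixel_size_um=px)


def disk_image(shape=(128, 128), radius=50.0, inside=100.0, outside=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    c = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    img = np.where(np.hypot(yy - c[0], xx - c[1]) <= radius, inside, outside)
    return img


class TestSegmentNucleus:
    def test_disk_areas_match_geometry(self):
        img = disk_image()
        seg = segment_nucleus(pair_from(img, img), ring_width_px=3)
        assert seg.nucleus_mask.sum() == pytest.approx(math.pi * 50**2, rel=0.10)
        assert seg.ne_ring_mask.sum() == pytest.approx(2 * math.pi * 50 * 3, rel=0.10)

    def test_blank_image_is_segmentation_error(self):
        blank = np.zeros((64, 64))
        with pytest.raises(SegmentationError):
            segment_nucleus(pair_from(blank, blank))

    def test_ring_and_nucleoplasm_partition_nucleus(self):
        img = disk_image() + np.random.default_rng(0).normal(0, 2, (128, 128))
        seg = segment_nucleus(pair_from(img, img), ring_width_px=4)
        seg.validate()  # disjoint and exhaustive by construction
        assert not (seg.ne_ring_mask & seg.nucleoplasm_mask).any()
        assert ((seg.ne_ring_mask | seg.nucleoplasm_mask) == seg.nucleus_mask).all()

    def test_largest_component_selected(self):
        img = disk_image(radius=40.0)
        img[5:10, 5:10] = 100.0  # small distractor blob
        seg = segment_nucleus(pair_from(img, img))
        assert not seg.nucleus_mask[5:10, 5:10].any()


class TestCoefficients:
    def test_pcc_perfect_affine(self, rng):
        a = rng.uniform(0, 10, (16, 16))
        mask = np.ones_like(a, bool)
        assert pearson(pair_from(a, 2 * a + 3), mask) == pytest.approx(1.0)
        assert pearson(pair_from(a, -a), mask) == pytest.approx(-1.0)

    def test_pcc_hand_computed(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[2.0, 1.0], [4.0, 3.0]])
        assert pearson(pair_from(a, b), np.ones((2, 2), bool)) == pytest.approx(0.6)

    def test_pcc_zero_variance_raises(self):
        a = np.ones((4, 4))
        with pytest.raises(UndefinedResultError):
            pearson(pair_from(a, a), np.ones((4, 4), bool))

    def test_moc_identical_and_disjoint(self):
        a = np.array([[1.0, 2.0], [0.0, 3.0]])
        mask = np.ones((2, 2), bool)
        assert manders_overlap(pair_from(a, a), mask) == pytest.approx(1.0)
        b = np.array([[0.0, 0.0], [5.0, 0.0]])
        assert manders_overlap(pair_from(a, b), mask) == pytest.approx(0.0)

    def test_moc_hand_computed_one_over_sqrt2(self):
        a = np.array([[1.0, 1.0]])
        b = np.array([[1.0, 0.0]])
        assert manders_overlap(pair_from(a, b), np.ones((1, 2), bool)) == pytest.approx(
            1 / math.sqrt(2)
        )

    def test_moc_scale_invariance(self, rng):
        a = rng.uniform(0, 5, (8, 8))
        b = rng.uniform(0, 5, (8, 8))
        mask = np.ones((8, 8), bool)
        m = manders_overlap(pair_from(a, b), mask)
        assert manders_overlap(pair_from(7.3 * a, b), mask) == pytest.approx(m)
        assert manders_overlap(pair_from(a, 0.11 * b), mask) == pytest.approx(m)

    def test_m1_boundary_cases(self):
        a = np.array([[2.0, 2.0]])
        mask = np.ones((1, 2), bool)
        above = np.array([[1.0, 1.0]])
        below = np.array([[0.0, 0.0]])
        assert manders_m1_m2(pair_from(a, above), mask, threshold_b=0.5)[0] == 1.0
        assert manders_m1_m2(pair_from(a, below), mask, threshold_b=0.5)[0] == 0.0

    def test_m1_hand_computed_half(self):
        a = np.array([[2.0, 2.0]])
        b = np.array([[1.0, 0.0]])
        m1, _ = manders_m1_m2(pair_from(a, b), np.ones((1, 2), bool), threshold_b=0.5)
        assert m1 == pytest.approx(0.5)


class TestQuantifyFoci:
    @staticmethod
    def image_with_disks(centers, radius=4.0, value=100.0, shape=(100, 100)):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        img = np.zeros(shape)
        for cy, cx in centers:
            img[np.hypot(yy - cy, xx - cx) <= radius] = value
        return img

    def test_counts_well_separated_disks(self):
        centers = [(20, 20), (20, 70), (50, 45), (80, 20), (80, 70)]
        img = self.image_with_disks(centers)
        stats = quantify_foci(img, np.ones((100, 100), bool), threshold="fixed", fixed_threshold=50.0)
        assert stats.n_foci == 5
        assert stats.mean_focus_area_um2 == pytest.approx(stats.total_area_um2 / 5)

    def test_merging_two_disks_reduces_count_increases_mean_area(self):
        separate = self.image_with_disks([(20, 20), (20, 70), (70, 45)])
        merged = self.image_with_disks([(20, 20), (20, 26), (70, 45)])
        mask = np.ones((100, 100), bool)
        s1 = quantify_foci(separate, mask, threshold="fixed", fixed_threshold=50.0)
        s2 = quantify_foci(merged, mask, threshold="fixed", fixed_threshold=50.0)
        assert s2.n_foci == s1.n_foci - 1
        assert s2.mean_focus_area_um2 > s1.mean_focus_area_um2

    def test_fewer_bigger_foci_direction(self):
        # same total area split into many-small vs few-large
        many = self.image_with_disks([(20, 20), (20, 60), (60, 20), (60, 60)], radius=4.0)
        few = self.image_with_disks([(30, 30), (70, 70)], radius=4.0 * math.sqrt(2))
        mask = np.ones((100, 100), bool)
        s_many = quantify_foci(many, mask, threshold="fixed", fixed_threshold=50.0)
        s_few = quantify_foci(few, mask, threshold="fixed", fixed_threshold=50.0)
        assert s_few.n_foci < s_many.n_foci
        assert s_few.mean_focus_area_um2 > s_many.mean_focus_area_um2
        assert s_few.total_area_um2 == pytest.approx(s_many.total_area_um2, rel=0.10)

    def test_min_area_filters_specks(self):
        img = self.image_with_disks([(50, 50)], radius=5.0)
        img[10, 10] = 100.0  # single-pixel speck
        stats = quantify_foci(img, np.ones((100, 100), bool), threshold="fixed",
                              fixed_threshold=50.0, min_area_px=4)
        assert stats.n_foci == 1

    def test_pixel_size_converts_area(self):
        img = self.image_with_disks([(50, 50)], radius=5.0)
        s = quantify_foci(img, np.ones((100, 100), bool), threshold="fixed",
                          fixed_threshold=50.0, pixel_size_um=0.2)
        px = int((img > 50).sum())
        assert s.total_area_um2 == pytest.approx(px * 0.04)

    def test_zero_foci_allowed(self):
        stats = quantify_foci(np.zeros((20, 20)), np.ones((20, 20), bool))
        assert stats.n_foci == 0 and stats.mean_focus_area_um2 == 0.0


class TestCompareFociGroups:
    def test_identical_groups_p_near_one(self):
        g = [FociStats(5, 1.0, 10.0, 0.2) for _ in range(5)]
        rep = compare_foci_groups(g, list(g), metric="n_foci")
        assert rep["p_value"] == pytest.approx(1.0)

    def test_strong_difference_highly_significant(self, rng):
        g1 = [FociStats(int(n), 1.0, 1.0, 0.1) for n in rng.normal(10, 1, 10)]
        g2 = [FociStats(int(n), 1.0, 1.0, 0.1) for n in rng.normal(5, 1, 10)]
        rep = compare_foci_groups(g1, g2, metric="n_foci")
        assert rep["p_value"] < 0.005
        assert rep["significance"] == "***"

    def test_unknown_metric_raises(self):
        g = [FociStats(5, 1.0, 10.0, 0.2)] * 3
        with pytest.raises(ParameterError):
            compare_foci_groups(g, g, metric="sparkle")

    def test_small_groups_raise(self):
        g = [FociStats(5, 1.0, 10.0, 0.2)] * 2
        with pytest.raises(ParameterError):
            compare_foci_groups(g, g, metric="n_foci")
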