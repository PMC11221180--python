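"""Contour statistics, fragmentation factor, rule-table repair, partitioning."""

import numpy as np
import pytest
from skimage import draw

from pneumostage import maskops
from pneumostage.phantom import DefectSpec, inject_defects


def _disc_mask(size, center, radius):
    m = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk(center, radius, shape=(size, size))
    m[rr, cc] = True
    return m


class TestExtractContours:
    def test_two_disjoint_ellipses_give_two_contours(self, two_ellipse_mask):
        assert maskops.extract_contours(two_ellipse_mask).n == 2

    def test_empty_mask_gives_zero(self):
        assert maskops.extract_contours(np.zeros((32, 32), bool)).n == 0

    def test_hole_and_fragment_each_add_a_contour(self, two_ellipse_mask):
        m = two_ellipse_mask.copy()
        rr, cc = draw.disk((60, 40), 3)
        m[rr, cc] = False                      # hole inside the left lung
        rr, cc = draw.disk((8, 120), 3, shape=m.shape)
        m[rr, cc] = True                       # fragment outside
        assert maskops.extract_contours(m).n == 4


class TestFragmentationFactor:
    def test_square_ideal_geometry(self):
        s = 60
        m = np.zeros((100, 100), bool)
        m[20:20 + s, 20:20 + s] = True
        lam = maskops.fragmentation_factor(maskops.extract_contours(m))
        assert lam == pytest.approx(4 / s, rel=0.05)

    def test_disc_ideal_geometry(self):
        r = 30
        lam = maskops.fragmentation_factor(maskops.extract_contours(_disc_mask(100, (50, 50), r)))
        assert lam == pytest.approx(2 / r, rel=0.05)

    def test_fragmentation_increases_at_fixed_area(self):
        # one 40x40 square vs two 28x28 squares (~same total area)
        one = np.zeros((120, 120), bool)
        one[10:50, 10:50] = True
        two = np.zeros((120, 120), bool)
        two[10:38, 10:38] = True
        two[70:98, 70:98] = True
        lam1 = maskops.fragmentation_factor(maskops.extract_contours(one))
        lam2 = maskops.fragmentation_factor(maskops.extract_contours(two))
        assert lam2 > lam1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            maskops.fragmentation_factor(maskops.extract_contours(np.zeros((8, 8), bool)))


class TestSelectOperatorSize:
    @pytest.mark.parametrize("n,lam,expected", [
        (2, 0.1, None), (2, 0.001, None),
        (3, 0.02, 3), (4, 0.02, 3), (5, 0.0319, 3),
        (3, 0.032, 5), (4, 0.036, 5), (5, 0.04, 5),   # closed middle interval
        (3, 0.0401, 7), (4, 0.1, 7),
        (6, 0.001, 9), (7, 0.001, 9), (12, 0.5, 9),
    ])
    def test_rule_table(self, n, lam, expected):
        assert maskops.select_operator_size(n, lam) == expected

    def test_fewer_than_two_contours_rejected(self):
        with pytest.raises(ValueError):
            maskops.select_operator_size(1, 0.05)

    def test_monotone_in_lambda_for_midrange_counts(self):
        sizes = {None: 0, 3: 3, 5: 5, 7: 7, 9: 9}
        for n in (3, 4, 5):
            chosen = [sizes[maskops.select_operator_size(n, lam)]
                      for lam in np.linspace(0.001, 0.2, 50)]
            assert chosen == sorted(chosen)


class TestRepairMask:
    def test_none_is_identity(self, two_ellipse_mask):
        assert np.array_equal(maskops.repair_mask(two_ellipse_mask, None), two_ellipse_mask)

    def test_open_close_fixed_point_on_large_rectangle(self):
        m = np.zeros((64, 64), bool)
        m[10:50, 10:50] = True
        assert np.array_equal(maskops.repair_mask(m, 3), m)

    def test_small_hole_and_fragment_removed(self, two_ellipse_mask):
        d = inject_defects(two_ellipse_mask,
                           DefectSpec(n_holes=1, hole_radius=1, n_fragments=1,
                                      fragment_area=9, seed=4))
        assert maskops.extract_contours(d).n == 4
        repaired = maskops.repair_mask(d, 5)
        assert maskops.extract_contours(repaired).n == 2

    def test_invalid_size_rejected(self, two_ellipse_mask):
        with pytest.raises(ValueError):
            maskops.repair_mask(two_ellipse_mask, 4)


class TestPartitionSix:
    def test_equal_split(self):
        m = np.zeros((1000, 800), bool)
        m[50:950, 100:700] = True  # bbox 900 tall x 600 wide
        part = maskops.partition_six(m)
        for rect in part.rects.values():
            r0, r1, c0, c1 = rect
            assert (r1 - r0, c1 - c0) == (300, 300)

    def test_remainder_first_convention(self):
        m = np.zeros((950, 700), bool)
        m[10:911, 20:621] = True  # bbox 901 x 601
        part = maskops.partition_six(m)
        heights = sorted({r[1] - r[0] for r in part.rects.values()}, reverse=True)
        widths = sorted({r[3] - r[2] for r in part.rects.values()}, reverse=True)
        assert widths == [301, 300]
        assert heights == [301, 300]
        # remainder goes to the first row/column
        assert part.rects["ul"][1] - part.rects["ul"][0] == 301
        assert part.rects["ul"][3] - part.rects["ul"][2] == 301

    def test_rectangles_tile_bounding_box_exactly(self, two_ellipse_mask):
        part = maskops.partition_six(two_ellipse_mask)
        r0, r1, c0, c1 = part.bbox
        cover = np.zeros((r1 - r0, c1 - c0), dtype=int)
        for rr0, rr1, cc0, cc1 in part.rects.values():
            cover[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] += 1
        assert (cover == 1).all()

    def test_pixels_outside_mask_zeroed(self, small_phantom):
        part = maskops.partition_six(small_phantom.mask, small_phantom.image)
        m = maskops.partition_six(small_phantom.mask)
        for key in maskops.SUBREGION_KEYS:
            outside = m.crops[key] == 0
            assert (part.crops[key][outside] == 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            maskops.partition_six(np.zeros((32, 32), bool))
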