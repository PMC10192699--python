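"""Self-comparison stage: differencing, opening, components, prior filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from oracles import flood_fill_components
from pipettewatch.config import PipelineConfig
from pipettewatch.selfcomp import (
    ContourBox,
    diff_frame,
    extract_contour_boxes,
    filter_contours,
    median_width_denoise,
    open_mask,
)
from pipettewatch.video import Box


def cbox(x, y, w, h, area=None, slot=None):
    return ContourBox(box=Box(x, y, w, h), area=area if area is not None else w * h,
                      slot=slot)


class TestDiffFrame:
    def test_identical_crops_give_empty_mask(self):
        crop = np.random.default_rng(0).integers(0, 255, (20, 30, 3)).astype(np.uint8)
        assert not diff_frame(crop, crop, 25).any()

    def test_block_difference_localised(self):
        a = np.full((40, 40, 3), 50, dtype=np.uint8)
        b = a.copy()
        b[5:15, 10:30] = 150
        mask = diff_frame(b, a, 25)
        expected = np.zeros((40, 40), dtype=bool)
        expected[5:15, 10:30] = True
        assert np.array_equal(mask, expected)

    def test_unreachable_threshold(self):
        a = np.zeros((10, 10, 3), dtype=np.uint8)
        b = np.full((10, 10, 3), 255, dtype=np.uint8)
        assert not diff_frame(b, a, 255).any()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            diff_frame(np.zeros((4, 4, 3)), np.zeros((5, 4, 3)), 25)


class TestOpenMask:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 4] = True
        assert not open_mask(mask, 3).any()

    def test_solid_square_preserved(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        assert np.array_equal(open_mask(mask, 3), mask)

    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(1)
        mask = rng.random((15, 15)) > 0.5
        assert np.array_equal(open_mask(mask, 1), mask)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            open_mask(np.zeros((5, 5), dtype=bool), 4)

    def test_border_touching_column_survives(self):
        # a liquid column reaching the crop edge must not be eaten there
        mask = np.zeros((20, 20), dtype=bool)
        mask[10:20, 3:11] = True
        assert np.array_equal(open_mask(mask, 5), mask)

    @settings(derandomize=True, max_examples=60)
    @given(
        mask=hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2,
                                               min_side=6, max_side=24)),
        k=st.sampled_from([3, 5]),
    )
    def test_idempotent_and_anti_extensive(self, mask, k):
        opened = open_mask(mask, k)
        assert not (opened & ~mask).any()  # anti-extensive
        assert np.array_equal(open_mask(opened, k), opened)  # idempotent


class TestExtractContourBoxes:
    def test_two_disjoint_rectangles(self):
        mask = np.zeros((20, 30), dtype=bool)
        mask[2:6, 3:8] = True
        mask[10:18, 20:25] = True
        boxes = extract_contour_boxes(mask)
        assert [(c.box.x, c.box.y, c.box.w, c.box.h, c.area) for c in boxes] == [
            (3, 2, 5, 4, 20),
            (20, 10, 5, 8, 40),
        ]

    def test_empty_mask(self):
        assert extract_contour_boxes(np.zeros((5, 5), dtype=bool)) == []

    def test_l_shape_has_tight_box_and_smaller_area(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:4] = True
        mask[6:8, 2:9] = True
        (c,) = extract_contour_boxes(mask)
        assert (c.box.x, c.box.y, c.box.w, c.box.h) == (2, 2, 7, 6)
        assert c.area < c.box.w * c.box.h

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(4, 33)), int(rng.integers(4, 33)))
        mask = rng.random(shape) < 0.35
        got = [
            (c.box.x, c.box.y, c.box.w, c.box.h, c.area)
            for c in extract_contour_boxes(mask)
        ]
        assert got == flood_fill_components(mask.tolist())


class TestFilterContours:
    config = PipelineConfig(n_pipettes=8, r_min=0.5, growth_tolerance=2)
    no_prev = [None] * 8

    def test_largest_n_survive_area_ranking(self):
        # 10 tall candidates in distinct slots; the two smallest must vanish
        boxes = [cbox(10 * i, 0, 4, 10 + i, area=4 * (10 + i)) for i in range(10)]
        out = filter_contours(boxes, self.no_prev, self.config, crop_width=100)
        kept_areas = {c.area for c in out if c is not None}
        top8 = {4 * (10 + i) for i in range(2, 10)}
        assert kept_areas and kept_areas <= top8  # the 2 smallest never survive

    def test_flat_box_dropped_by_aspect_ratio(self):
        boxes = [cbox(0, 0, 10, 4)]  # h/w = 0.4 < 0.5
        out = filter_contours(boxes, self.no_prev, self.config, crop_width=80)
        assert all(c is None for c in out)

    def test_shrinking_column_dropped_by_growth_prior(self):
        prev = [None] * 8
        prev[0] = cbox(1, 0, 4, 30, slot=0)
        candidate = [cbox(1, 0, 4, 20)]
        out = filter_contours(candidate, prev, self.config, crop_width=80)
        assert out[0] is None
        # within tolerance is kept: 29 >= 30 - 2
        out = filter_contours([cbox(1, 0, 4, 29)], prev, self.config, crop_width=80)
        assert out[0] is not None

    def test_slot_assignment_keeps_largest_per_slot(self):
        # both candidates fall in slot 0 (slot width 10)
        boxes = [cbox(1, 0, 4, 8), cbox(3, 0, 4, 20)]
        out = filter_contours(boxes, self.no_prev, self.config, crop_width=80)
        assert out[0].box.h == 20
        assert sum(c is not None for c in out) == 1

    def test_invalid_pipette_count(self):
        with pytest.raises(ValueError):
            filter_contours([], [], PipelineConfig(n_pipettes=0), crop_width=80)

    def test_at_most_n_present_slots(self):
        rng = np.random.default_rng(2)
        boxes = [
            cbox(int(rng.integers(0, 76)), 0, 4, int(rng.integers(4, 40)))
            for _ in range(30)
        ]
        out = filter_contours(boxes, self.no_prev, self.config, crop_width=80)
        assert len(out) == 8
        assert sum(c is not None for c in out) <= 8


class TestMedianWidthDenoise:
    def test_outlier_width_snapped_to_median(self):
        slots = [cbox(0, 0, 10, 20), cbox(20, 0, 10, 20), cbox(40, 0, 11, 20),
                 cbox(60, 0, 40, 20), cbox(100, 0, 10, 20), None]
        out = median_width_denoise(slots)
        assert [c.box.w for c in out if c is not None] == [10] * 5

    def test_single_box_unchanged(self):
        slots = [cbox(5, 0, 17, 20), None]
        out = median_width_denoise(slots)
        assert out[0].box.w == 17

    def test_even_count_averages_central_pair(self):
        slots = [cbox(0, 0, 10, 20), cbox(30, 0, 20, 20)]
        out = median_width_denoise(slots)
        assert [c.box.w for c in out] == [15, 15]

    def test_all_absent_returned_unchanged(self):
        assert median_width_denoise([None, None]) == [None, None]

    def test_preserves_heights_slots_and_count(self):
        slots = [cbox(0, 0, 9, 12, slot=0), None, cbox(22, 3, 15, 31, slot=2)]
        out = median_width_denoise(slots)
        assert sum(c is not None for c in out) == 2
        assert [c.box.h for c in out if c is not None] == [12, 31]
        assert [c.slot for c in out if c is not None] == [0, 2]

    def test_x_center_preserved(self):
        slots = [cbox(10, 0, 9, 12), cbox(40, 0, 13, 12), cbox(70, 0, 21, 12)]
        out = median_width_denoise(slots)
        for before, after in zip(slots, out):
            assert abs(before.box.center[0] - after.box.center[0]) <= 0.5
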