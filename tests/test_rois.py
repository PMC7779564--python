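"""Disc rasterisation, searching areas, reference ROIs and Dice overlap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coeruleus.exceptions import EmptyMaskError, UndefinedDiceError
from coeruleus.phantom import DEFAULT_GRID
from coeruleus.rois import (
    SearchSpec,
    ReferenceSpec,
    build_reference_roi,
    build_searching_area,
    build_searching_areas,
    constant_center_path,
    dice,
    disc_coverage_fractions,
    disc_rect_overlap_area,
    hemisphere_split,
    rasterize_disc,
)
from coeruleus.volumes import GridSpec, RoiMask, mask_volume_mm3


def brute_force_disc_count(center, radius, grid, k):
    """Oracle: scan every voxel centre on the slice."""
    xs = grid.axis_coords_mm(0)
    ys = grid.axis_coords_mm(1)
    count = 0
    for x in xs:
        for y in ys:
            if (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2 + 1e-9:
                count += 1
    return count


class TestDiscRectOverlap:
    def test_rect_containing_disc(self):
        assert disc_rect_overlap_area(0, 0, 1.0, -2, 2, -2, 2) == pytest.approx(math.pi)

    def test_disc_containing_rect(self):
        assert disc_rect_overlap_area(0, 0, 10.0, -1, 1, -1, 1) == pytest.approx(4.0)

    def test_half_plane_split(self):
        assert disc_rect_overlap_area(0, 0, 1.0, 0, 5, -5, 5) == pytest.approx(math.pi / 2)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        cx=st.floats(-1, 1),
        cy=st.floats(-1, 1),
        r=st.floats(0.2, 2.0),
        x0=st.floats(-2, 0.5),
        y0=st.floats(-2, 0.5),
        w=st.floats(0.1, 2.5),
        h=st.floats(0.1, 2.5),
    )
    def test_matches_monte_carlo(self, cx, cy, r, x0, y0, w, h):
        exact = disc_rect_overlap_area(cx, cy, r, x0, x0 + w, y0, y0 + h)
        rng = np.random.default_rng(12345)
        pts = rng.random((40000, 2)) * [w, h] + [x0, y0]
        inside = ((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2) <= r * r
        mc = inside.mean() * w * h
        assert exact == pytest.approx(mc, abs=4 * w * h / math.sqrt(40000) + 1e-3)

    def test_coverage_fractions_sum_to_disc_area(self, default_grid):
        ii, jj, fr = disc_coverage_fractions((4.1, -1.3), 1.25, default_grid)
        assert fr.sum() * 0.25 == pytest.approx(math.pi * 1.25**2, rel=1e-9)
        assert np.all((fr > 0) & (fr <= 1 + 1e-12))


class TestRasterizeDisc:
    def test_2p5mm_disc_on_voxel_centre_covers_21_voxels(self, default_grid):
        # brute-force over the 5x5 neighbourhood: corner voxels sit at
        # distance sqrt(2) * 1.0 mm > 1.25 mm and are excluded
        mask = rasterize_disc((4.25, -1.25), 2.5, default_grid, 20)
        assert mask.n_voxels == 21
        assert mask.n_voxels == brute_force_disc_count((4.25, -1.25), 1.25, default_grid, 20)

    def test_subvoxel_disc_is_single_voxel(self, default_grid):
        assert rasterize_disc((4.25, -1.25), 0.5, default_grid, 5).n_voxels == 1

    def test_off_centre_disc_matches_brute_force(self, default_grid):
        # centred between voxel centres the count differs from 21; the
        # brute-force oracle is the reference either way
        count = rasterize_disc((4.0, -1.0), 2.5, default_grid, 5).n_voxels
        assert count == brute_force_disc_count((4.0, -1.0), 1.25, default_grid, 5)
        assert count != 21

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        cx=st.floats(-6, 6),
        cy=st.floats(-6, 6),
        d=st.floats(0.6, 4.0),
        k=st.integers(0, 39),
    )
    def test_matches_centre_scan_oracle(self, cx, cy, d, k):
        oracle = brute_force_disc_count((cx, cy), d / 2, DEFAULT_GRID, k)
        try:
            mask = rasterize_disc((cx, cy), d, DEFAULT_GRID, k)
        except EmptyMaskError:
            assert oracle == 0  # small disc between voxel centres
            return
        assert mask.n_voxels == oracle
        assert set(np.unique(mask.indices()[:, 2])) == {k}

    def test_disc_outside_grid_raises(self, default_grid):
        with pytest.raises(EmptyMaskError):
            rasterize_disc((100.0, 100.0), 1.0, default_grid, 5)


class TestSearchingArea:
    def test_default_spec_volume_is_70p88_mm3(self, default_grid):
        spec = SearchSpec()
        mask = build_searching_area(spec, default_grid, "left")
        assert mask.n_voxels == 567
        assert mask_volume_mm3(mask) == pytest.approx(70.875)
        assert round(mask_volume_mm3(mask), 2) == 70.88

    def test_slab_spans_27_slices_and_13p5_mm(self):
        spec = SearchSpec()
        assert spec.n_slices == 27
        assert spec.extent_mm == pytest.approx(13.5)

    def test_single_slice_spec_is_one_disc(self, default_grid):
        spec = SearchSpec(rostral_slice=100, caudal_slice=100)
        mask = build_searching_area(spec, default_grid, "right")
        disc = rasterize_disc((4.25, -1.25), 2.5, default_grid, 100, spec.convention)
        assert mask.n_voxels == disc.n_voxels == 21

    def test_hemispheres_disjoint(self, default_grid):
        areas = build_searching_areas(SearchSpec(), default_grid)
        assert areas["left"].intersection(areas["right"]).is_empty


class TestReferenceRoi:
    def test_default_cube_is_72_mm3(self, default_grid):
        spec = ReferenceSpec("central_pt", "cube", (0.0, -5.0, -22.5))
        mask = build_reference_roi(spec, default_grid)
        assert mask.n_voxels == 576  # 8 x 8 x 9 at 0.5 mm
        assert mask_volume_mm3(mask) == pytest.approx(72.0)

    def test_unit_cube_is_8_voxels(self, default_grid):
        spec = ReferenceSpec("c", "cube", (0.0, -5.0, -22.25), size_mm=(1.0, 1.0, 1.0))
        assert build_reference_roi(spec, default_grid).n_voxels == 8

    def test_cube_off_grid_raises(self, default_grid):
        spec = ReferenceSpec("c", "cube", (30.0, 0.0, -22.5))
        with pytest.raises(EmptyMaskError):
            build_reference_roi(spec, default_grid)

    def test_lc_shaped_clone_volume_matches_searching_area(self, default_grid):
        search = SearchSpec()
        area = build_searching_area(search, default_grid, "left")
        clone = build_reference_roi(
            ReferenceSpec("left_scp", "lc_shaped", (-7.25, -1.25, 0), source=search),
            default_grid,
        )
        assert clone.n_voxels == area.n_voxels
        assert mask_volume_mm3(clone) == pytest.approx(mask_volume_mm3(area))

    def test_cube_and_disc_volumes_matched_within_slab_tolerance(self, default_grid):
        # the two reference geometries are volume-matched by design:
        # 70.875 vs 72.0 mm^3 differ by less than one voxel per slice
        area = build_searching_area(SearchSpec(), default_grid, "left")
        cube = build_reference_roi(
            ReferenceSpec("c", "cube", (0.0, -5.0, -22.5)), default_grid
        )
        diff = abs(mask_volume_mm3(cube) - mask_volume_mm3(area))
        assert diff <= 27 * default_grid.voxel_volume_mm3


class TestDice:
    def _mask(self, grid, flat_indices):
        data = np.zeros(grid.shape, dtype=bool)
        data.flat[list(flat_indices)] = True
        return RoiMask(grid, data)

    def test_identical_masks_give_one(self, small_grid):
        m = self._mask(small_grid, range(10))
        assert dice(m, m) == 1.0

    def test_disjoint_masks_give_zero(self, small_grid):
        a = self._mask(small_grid, range(5))
        b = self._mask(small_grid, range(10, 15))
        assert dice(a, b) == 0.0

    def test_hand_counted_overlap(self, small_grid):
        a = self._mask(small_grid, [0, 1, 2, 3])
        b = self._mask(small_grid, [2, 3, 10, 11])
        assert dice(a, b) == pytest.approx(0.5)  # 2*2 / (4+4)

    def test_both_empty_undefined(self, small_grid):
        e = RoiMask.empty(small_grid)
        with pytest.raises(UndefinedDiceError):
            dice(e, e)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetric_and_monotone(self, seed):
        grid = GridSpec((6, 6, 6), (0.5, 0.5, 0.5))
        rng = np.random.default_rng(seed)
        a = RoiMask(grid, rng.random(grid.shape) < 0.4)
        b = RoiMask(grid, rng.random(grid.shape) < 0.4)
        if a.n_voxels + b.n_voxels == 0:
            return
        assert dice(a, b) == dice(b, a)
        inter = a.intersection(b)
        if not inter.is_empty:
            # removing an intersection voxel from b cannot increase Dice
            data = b.data.copy()
            idx = tuple(inter.indices()[0])
            data[idx] = False
            if data.any() or a.n_voxels:
                assert dice(a, RoiMask(grid, data)) <= dice(a, b) + 1e-12


class TestHemisphereSplit:
    def test_midline_voxels_excluded(self):
        grid = GridSpec((5, 3, 3), (0.5, 0.5, 0.5), (-1.0, 0.0, 0.0))  # x = -1..1, centre at 0
        mask = RoiMask(grid, np.ones(grid.shape, bool))
        halves = hemisphere_split(mask)
        assert halves["left"].n_voxels == 2 * 9
        assert halves["right"].n_voxels == 2 * 9
        assert halves["left"].intersection(halves["right"]).is_empty
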