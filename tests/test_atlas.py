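"""Threshold segmentation, peak extraction and the probabilistic atlas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coeruleus.atlas import (
    atlas_cnr,
    build_prob_atlas,
    segment_lc,
    slice_profiles,
    threshold_atlas,
)
from coeruleus.exceptions import ConfigurationError, EmptyMaskError
from coeruleus.metrics import ReferenceStats, cnr_map
from coeruleus.phantom import DEFAULT_GRID
from coeruleus.rois import SearchSpec, build_searching_areas
from coeruleus.volumes import GridSpec, ImageVolume, RoiMask, grid_k_for_slice

STATS = ReferenceStats("ref", 100.0, 4.0, 25.0, 576)  # threshold at k=5 -> 120


@pytest.fixture(scope="module")
def searching():
    return build_searching_areas(SearchSpec(), DEFAULT_GRID)


def _segment(values, searching, threshold=120.0):
    vol = ImageVolume(DEFAULT_GRID, values, "mt_on")
    return segment_lc(vol, searching, threshold, cnr_map(vol, STATS, "s1"), "s1")


class TestSegmentLc:
    def test_subthreshold_cohort_yields_empty_masks_and_missing_peaks(self, searching):
        res = _segment(np.full(DEFAULT_GRID.shape, 100.0), searching)
        assert res.mask_combined().is_empty
        assert all(p.missing for p in res.peaks)
        assert (res.counts["count"] == 0).all()

    def test_hand_built_slice_peak(self, searching):
        values = np.full(DEFAULT_GRID.shape, 100.0)
        k = grid_k_for_slice(99, DEFAULT_GRID)
        # three suprathreshold voxels in the left searching area on slice 99
        left_idx = [tuple(v) for v in searching["left"].indices() if v[2] == k][:3]
        for idx, v in zip(left_idx, (121.0, 130.0, 125.0)):
            values[idx] = v
        res = _segment(values, searching)
        assert res.masks["left"].n_voxels == 3
        peak = next(p for p in res.peaks if p.slice_index == 99 and p.hemisphere == "left")
        assert values[peak.voxel_index] == 130.0
        assert peak.cnr == pytest.approx((130.0 - 100.0) / 4.0)  # == 7.5

    def test_every_segmented_voxel_is_in_search_area_and_above_threshold(
        self, small_cohort_report
    ):
        seg = small_cohort_report["_objects"]["seg_results"][0]
        searching = build_searching_areas(SearchSpec(), DEFAULT_GRID)
        for hemi in ("left", "right"):
            assert seg.masks[hemi].difference(searching[hemi]).is_empty

    def test_counts_conserve_mask_sizes(self, small_cohort_report):
        for seg in small_cohort_report["_objects"]["seg_results"]:
            by_hemi = seg.counts.groupby("hemisphere")["count"].sum()
            for hemi in ("left", "right"):
                assert by_hemi[hemi] == seg.masks[hemi].n_voxels

    def test_peak_cnr_dominates_slice(self, small_cohort_report):
        seg = small_cohort_report["_objects"]["seg_results"][1]
        cnr = small_cohort_report["_objects"]["cnr_maps"][1]
        for p in seg.peaks:
            if p.missing:
                continue
            k = p.voxel_index[2]
            in_slice = seg.masks[p.hemisphere].data[:, :, k]
            assert p.cnr >= np.nanmax(cnr.volume.values[:, :, k][in_slice]) - 1e-12

    def test_group_count_profile_peaks_centrally(self, small_cohort_report):
        prof = small_cohort_report["_tables"]["slice_profiles"]
        mean_counts = prof.groupby("slice")["count"].mean()
        slices = sorted(mean_counts.index)
        third = len(slices) // 3
        caudal = mean_counts[slices[:third]].mean()
        central = mean_counts[slices[third : -third]].mean()
        rostral = mean_counts[slices[-third:]].mean()
        assert central > rostral and central > caudal

    def test_empty_searching_area_is_a_configuration_error(self, searching):
        bad = dict(searching)
        bad["left"] = RoiMask.empty(DEFAULT_GRID)
        vol = ImageVolume(DEFAULT_GRID, np.zeros(DEFAULT_GRID.shape), "mt_on")
        with pytest.raises(ConfigurationError):
            segment_lc(vol, bad, 120.0, cnr_map(vol, STATS), "s")


class TestSliceProfiles:
    def test_long_format_columns_and_sums(self, small_cohort_report):
        seg = small_cohort_report["_objects"]["seg_results"][0]
        prof = slice_profiles(seg)
        assert {"subject_id", "slice", "hemisphere", "count", "peak_x", "peak_cnr"} <= set(
            prof.columns
        )
        assert prof["count"].sum() == seg.mask_combined().n_voxels


def _random_masks(n, seed, p=0.2):
    grid = GridSpec((6, 6, 5), (0.5, 0.5, 0.5))
    rng = np.random.default_rng(seed)
    return [RoiMask(grid, rng.random(grid.shape) < p) for _ in range(n)]


class TestProbAtlas:
    def test_single_subject_atlas_equals_its_mask(self):
        (mask,) = _random_masks(1, 4)
        atlas = build_prob_atlas([mask])
        np.testing.assert_array_equal(atlas.volume.values, mask.data.astype(float))

    def test_modal_voxel_shared_by_46_of_53_gives_86p79_percent(self):
        grid = GridSpec((6, 6, 5), (0.5, 0.5, 0.5))
        masks = []
        for i in range(53):
            data = np.zeros(grid.shape, dtype=bool)
            data[1, 1, 1] = i < 46  # the modal voxel
            data[2 + (i % 3), 2, 2] = True
            masks.append(RoiMask(grid, data))
        atlas = build_prob_atlas(masks, 53)
        assert round(atlas.max_probability * 100, 2) == 86.79

    def test_probabilities_are_exact_multiples_of_one_over_n(self):
        masks = _random_masks(7, 11)
        atlas = build_prob_atlas(masks)
        scaled = atlas.volume.values * 7
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-12)

    def test_probability_mass_conserves_mask_sizes(self):
        masks = _random_masks(9, 12)
        atlas = build_prob_atlas(masks)
        assert atlas.volume.values.sum() * 9 == pytest.approx(
            sum(m.n_voxels for m in masks)
        )

    def test_wrong_count_or_empty_list_rejected(self):
        masks = _random_masks(3, 13)
        with pytest.raises(ConfigurationError):
            build_prob_atlas(masks, 5)
        with pytest.raises(ConfigurationError):
            build_prob_atlas([])


class TestThresholdAtlas:
    def test_zero_threshold_keeps_union(self):
        masks = _random_masks(6, 21)
        atlas = build_prob_atlas(masks)
        union = masks[0]
        for m in masks[1:]:
            union = union.union(m)
        np.testing.assert_array_equal(threshold_atlas(atlas, 0).data, union.data)

    def test_above_max_probability_is_empty(self):
        atlas = build_prob_atlas(_random_masks(6, 22))
        assert threshold_atlas(atlas, atlas.max_probability + 0.01).is_empty

    def test_percent_and_fraction_are_equivalent(self):
        atlas = build_prob_atlas(_random_masks(8, 23))
        np.testing.assert_array_equal(
            threshold_atlas(atlas, 25).data, threshold_atlas(atlas, 0.25).data
        )

    def test_five_percent_of_53_means_three_or_more_subjects(self):
        grid = GridSpec((4, 4, 4), (0.5, 0.5, 0.5))
        masks = []
        for i in range(53):
            data = np.zeros(grid.shape, dtype=bool)
            data[0, 0, 0] = i < 2  # 2 subjects: below 5%
            data[1, 1, 1] = i < 3  # 3 subjects: exactly at the boundary
            masks.append(RoiMask(grid, data))
        mask = threshold_atlas(build_prob_atlas(masks, 53), 5)
        assert not mask.data[0, 0, 0]
        assert mask.data[1, 1, 1]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 1000),
        p1=st.floats(0, 1),
        p2=st.floats(0, 1),
    )
    def test_monotone_nesting(self, seed, p1, p2):
        lo, hi = sorted((p1, p2))
        atlas = build_prob_atlas(_random_masks(5, seed))
        assert threshold_atlas(atlas, hi).difference(threshold_atlas(atlas, lo)).is_empty

    def test_slice_profile_over_nonzero_voxels(self, small_cohort_report):
        atlas = small_cohort_report["_objects"]["atlas"]
        prof = atlas.slice_profile()
        assert (prof["max"] <= 1.0 + 1e-12).all()
        assert (prof["mean"] > 0).all()
        # lower-interpolated median is itself an attainable k/n probability
        scaled = prof["median"] * atlas.n_subjects
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-9)


class TestAtlasCnr:
    def test_constant_field_returns_constant(self):
        grid = GridSpec((4, 4, 4), (0.5, 0.5, 0.5))
        vol = ImageVolume(grid, np.full(grid.shape, 5.0), "cnr")
        from coeruleus.metrics import CnrMap

        mask = RoiMask(grid, np.ones(grid.shape, bool))
        assert atlas_cnr(CnrMap(vol, "s", "ref"), mask) == pytest.approx(5.0)

    def test_empty_mask_rejected(self):
        grid = GridSpec((4, 4, 4), (0.5, 0.5, 0.5))
        vol = ImageVolume(grid, np.zeros(grid.shape), "cnr")
        from coeruleus.metrics import CnrMap

        with pytest.raises(EmptyMaskError):
            atlas_cnr(CnrMap(vol, "s", "ref"), RoiMask.empty(grid))

    def test_core_atlas_cnr_exceeds_liberal_atlas_cnr(self, small_cohort_report):
        # the stringent (25%) template keeps the bright core, so its mean CNR
        # is higher than over the liberal (5%) template
        tab = small_cohort_report["_tables"]["cohort"]
        assert tab["atlas25_cnr_collapsed"].mean() > tab["atlas5_cnr_collapsed"].mean()
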