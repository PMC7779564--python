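"""Threshold-based nucleus segmentation and probabilistic atlas construction.

Segmentation is a binary decision inside the searching area: a voxel belongs
to the nucleus iff its (repeat-averaged) MT-on intensity is strictly greater
than the threshold T = Mean_REF + k x SD_REF. Per axial slice and hemisphere
the segmented voxel of maximal CNR is recorded as the peak (the nucleus
location on that slice); slices with no suprathreshold voxel yield explicit
missing records, never imputed values.

The probabilistic atlas is the voxelwise average of the cohort's binary
masks, so every probability is an exact multiple of 1/n. Thresholding at a
probability p keeps voxels with probability >= p (p may be given as a
fraction or a percent); p = 0 keeps the union of all masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyMaskError
from .metrics import CnrMap
from .volumes import (
    DEFAULT_SLICE_CONVENTION,
    ImageVolume,
    RoiMask,
    SliceConvention,
    check_compatible,
    mask_volume_mm3,
    slice_for_grid_k,
)


@dataclass
class PeakRecord:
    """Per-slice, per-hemisphere peak-CNR voxel (or an explicit missing marker)."""

    slice_index: int
    hemisphere: str
    voxel_index: tuple[int, int, int] | None
    world_xyz_mm: tuple[float, float, float] | None
    cnr: float  # NaN when missing
    tie: bool = False  # True when several voxels shared the maximal CNR

    @property
    def missing(self) -> bool:
        return self.voxel_index is None


@dataclass
class SegmentationResult:
    """Binary nucleus segmentation for one subject with per-slice bookkeeping."""

    subject_id: str
    masks: dict[str, RoiMask]  # per hemisphere
    threshold: float
    counts: pd.DataFrame  # columns: slice, hemisphere, count
    peaks: list[PeakRecord]

    def mask_combined(self) -> RoiMask:
        return self.masks["left"].union(self.masks["right"])

    def total_voxels(self, hemisphere: str | None = None) -> int:
        if hemisphere is None:
            return self.mask_combined().n_voxels
        return self.masks[hemisphere].n_voxels


def segment_lc(
    mt_on_avg: ImageVolume,
    searching: dict[str, RoiMask],
    threshold: float,
    cnr: CnrMap,
    subject_id: str = "",
    convention: SliceConvention = DEFAULT_SLICE_CONVENTION,
) -> SegmentationResult:
    """Segment the nucleus: searching-area voxels strictly above threshold.

    Peaks are taken among segmented voxels only, by maximal CNR; ties are
    broken deterministically by the lowest voxel index in (x, then y) scan
    order and flagged on the record.
    """
    for hemi, area in searching.items():
        if area.is_empty:
            raise ConfigurationError(f"searching area for {hemi!r} is empty")
    check_compatible(mt_on_avg, cnr.volume, *searching.values())

    grid = mt_on_avg.grid
    masks: dict[str, RoiMask] = {}
    count_rows = []
    peaks: list[PeakRecord] = []
    for hemi, area in searching.items():
        seg = area.data & (mt_on_avg.values > threshold)
        if mt_on_avg.missing is not None:
            seg &= ~mt_on_avg.missing
        masks[hemi] = RoiMask(grid, seg)
        ks = sorted({int(k) for k in np.unique(area.indices()[:, 2])})
        for k in ks:
            slice_no = slice_for_grid_k(k, grid, convention)
            in_slice = seg[:, :, k]
            n = int(in_slice.sum())
            count_rows.append({"slice": slice_no, "hemisphere": hemi, "count": n})
            if n == 0:
                peaks.append(PeakRecord(slice_no, hemi, None, None, float("nan")))
                continue
            ii, jj = np.nonzero(in_slice)
            cvals = cnr.volume.values[ii, jj, k]
            best = float(np.nanmax(cvals))
            winners = np.nonzero(cvals == best)[0]
            w = winners[0]  # lowest (x, y) scan-order index
            idx = (int(ii[w]), int(jj[w]), k)
            world = tuple(float(v) for v in grid.voxel_to_world(idx))
            peaks.append(PeakRecord(slice_no, hemi, idx, world, best, tie=len(winners) > 1))
    counts = pd.DataFrame(count_rows).sort_values(["hemisphere", "slice"]).reset_index(drop=True)
    return SegmentationResult(subject_id, masks, float(threshold), counts, peaks)


def slice_profiles(result: SegmentationResult) -> pd.DataFrame:
    """Long-format per-slice table: counts and peak coordinates/CNR."""
    peak_by_key = {(p.slice_index, p.hemisphere): p for p in result.peaks}
    rows = []
    for _, row in result.counts.iterrows():
        p = peak_by_key.get((row["slice"], row["hemisphere"]))
        rows.append(
            {
                "subject_id": result.subject_id,
                "slice": int(row["slice"]),
                "hemisphere": row["hemisphere"],
                "count": int(row["count"]),
                "peak_x": p.world_xyz_mm[0] if p and not p.missing else np.nan,
                "peak_y": p.world_xyz_mm[1] if p and not p.missing else np.nan,
                "peak_z": p.world_xyz_mm[2] if p and not p.missing else np.nan,
                "peak_cnr": p.cnr if p else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values(["hemisphere", "slice"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Probabilistic atlas


@dataclass
class ProbAtlas:
    """Voxelwise probability field built from n binary masks."""

    volume: ImageVolume  # probabilities in [0, 1]
    n_subjects: int
    counts: np.ndarray = field(repr=False)  # integer subject counts per voxel

    @property
    def max_probability(self) -> float:
        return float(self.volume.values.max())

    def slice_profile(
        self, convention: SliceConvention = DEFAULT_SLICE_CONVENTION
    ) -> pd.DataFrame:
        """Per-axial-slice mean/median/max probability over nonzero voxels.

        The median uses lower interpolation on the discrete k/n probability
        grid, so it is itself an attainable probability.
        """
        grid = self.volume.grid
        rows = []
        for k in range(grid.shape[2]):
            probs = self.volume.values[:, :, k]
            nz = probs[probs > 0]
            if nz.size == 0:
                continue
            rows.append(
                {
                    "slice": slice_for_grid_k(k, grid, convention),
                    "n_voxels": int(nz.size),
                    "mean": float(nz.mean()),
                    "median": float(np.quantile(nz, 0.5, method="lower")),
                    "max": float(nz.max()),
                }
            )
        return pd.DataFrame(rows).sort_values("slice").reset_index(drop=True)

    def threshold_report(self, p: float) -> dict:
        mask = threshold_atlas(self, p)
        return {
            "p": _normalise_p(p),
            "n_voxels": mask.n_voxels,
            "volume_mm3": mask_volume_mm3(mask),
        }


def build_prob_atlas(masks: Sequence[RoiMask], n_subjects: int | None = None) -> ProbAtlas:
    """Average binary masks into a probability field (exact multiples of 1/n)."""
    if len(masks) == 0:
        raise ConfigurationError("cannot build an atlas from zero masks")
    if n_subjects is None:
        n_subjects = len(masks)
    if n_subjects != len(masks):
        raise ConfigurationError(
            f"expected {n_subjects} masks, got {len(masks)}"
        )
    check_compatible(*masks)
    counts = np.zeros(masks[0].grid.shape, dtype=np.int64)
    for m in masks:
        counts += m.data
    probs = counts / float(n_subjects)
    return ProbAtlas(ImageVolume(masks[0].grid, probs, "prob"), n_subjects, counts)


def _normalise_p(p: float) -> float:
    """Accept a threshold as a fraction in [0, 1] or a percent in (1, 100]."""
    if p < 0 or p > 100:
        raise ValueError(f"threshold {p} out of range")
    return p / 100.0 if p > 1.0 else float(p)


def threshold_atlas(atlas: ProbAtlas, p: float) -> RoiMask:
    """Voxels with probability >= p; p = 0 keeps all nonzero-probability voxels.

    The comparison runs on integer subject counts (>= ceil(p * n) subjects),
    so float round-off in the probability grid cannot shift the boundary.
    """
    frac = _normalise_p(p)
    if frac <= 0.0:
        data = atlas.counts > 0
    else:
        k_min = math.ceil(frac * atlas.n_subjects - 1e-9)
        data = atlas.counts >= max(k_min, 1)
    return RoiMask(atlas.volume.grid, data)


def atlas_cnr(cnr: CnrMap, atlas_mask: RoiMask) -> float:
    """Mean CNR over a fixed atlas mask.

    The mask is the same for every subject regardless of their own
    segmentation — the volumetric-bias control: contrast is averaged within
    one spatially confined volume, so subjects with smaller segmentations
    are not flattered by dropping their weak voxels.
    """
    if atlas_mask.is_empty:
        raise EmptyMaskError("atlas mask is empty")
    check_compatible(cnr.volume, atlas_mask)
    vals = cnr.volume.values[atlas_mask.data]
    return float(np.nanmean(vals))


def segmentation_cnr(cnr: CnrMap, result: SegmentationResult) -> float:
    """Mean CNR over the subject's own segmented voxels (volume-confounded)."""
    mask = result.mask_combined()
    if mask.is_empty:
        return float("nan")
    return float(np.nanmean(cnr.volume.values[mask.data]))


__all__ = [
    "PeakRecord",
    "SegmentationResult",
    "ProbAtlas",
    "segment_lc",
    "slice_profiles",
    "build_prob_atlas",
    "threshold_atlas",
    "atlas_cnr",
    "segmentation_cnr",
]
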