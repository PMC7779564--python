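"""Signal metrics: region statistics, MTR and CNR maps, threshold, reference choice.

Conventions: all SDs are sample SDs (denominator n-1); SNR = mean/SD of a
region; MTR(%) = (MToff - MTon)/MToff x 100 voxelwise; the segmentation
threshold is T = Mean_REF + k x SD_REF with k = 5 by default (a more liberal
k = 4 variant is selectable); CNR = (V - Mean_REF)/SD_REF, so a voxel exactly
at the k-SD threshold has CNR exactly k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, DegenerateRegionError
from .volumes import ImageVolume, RoiMask, check_compatible, require_nonempty
from .rois import ReferenceSpec, build_reference_roi

DEFAULT_K_SD = 5.0


@dataclass
class ReferenceStats:
    """Summary statistics of one region for one subject."""

    roi_name: str
    mean_ref: float
    sd_ref: float
    snr: float
    n_voxels: int
    mtr_mean: float | None = None

    def __post_init__(self) -> None:
        if self.sd_ref <= 0:
            raise DegenerateRegionError(f"region {self.roi_name}: SD must be > 0")
        if self.n_voxels < 2:
            raise DegenerateRegionError(f"region {self.roi_name}: need >= 2 voxels")


@dataclass
class CnrMap:
    """Standardised-contrast map with its provenance."""

    volume: ImageVolume
    subject_id: str
    reference_name: str


def region_values(volume: ImageVolume, roi: RoiMask) -> np.ndarray:
    """Values of the volume inside the mask, excluding missing voxels."""
    check_compatible(volume, roi)
    require_nonempty(roi, "region")
    vals = volume.values[roi.data]
    if volume.missing is not None:
        vals = volume.values[roi.data & ~volume.missing]
    return vals


def region_stats(volume: ImageVolume, roi: RoiMask, name: str = "roi") -> ReferenceStats:
    """Mean, sample SD and SNR = mean/SD of a region.

    Raises :class:`DegenerateRegionError` for flat regions (SD == 0), which
    cannot provide a noise estimate.
    """
    vals = region_values(volume, roi)
    if vals.size < 2:
        raise DegenerateRegionError(f"region {name}: need >= 2 non-missing voxels")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        raise DegenerateRegionError(f"region {name}: zero variance")
    return ReferenceStats(name, mean, sd, mean / sd, int(vals.size))


def mtr_map(mt_off: ImageVolume, mt_on: ImageVolume, eps_frac: float = 1e-6) -> ImageVolume:
    """Voxelwise magnetisation-transfer ratio map in percent.

    Voxels whose MT-off signal is at or below ``eps_frac`` times the MT-off
    maximum are flagged missing rather than mapped to infinities.
    """
    check_compatible(mt_off, mt_on)
    off = mt_off.values
    eps = eps_frac * float(np.nanmax(np.abs(off))) if np.isfinite(off).any() else 0.0
    bad = ~(np.abs(off) > eps)
    if mt_off.missing is not None:
        bad |= mt_off.missing
    if mt_on.missing is not None:
        bad |= mt_on.missing
    if bad.all():
        raise DegenerateRegionError("MTR map empty: all MT-off voxels at or below epsilon")
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = (off - mt_on.values) / off * 100.0
    mtr = np.where(bad, np.nan, mtr)
    return ImageVolume(mt_off.grid, mtr, "mtr", missing=bad if bad.any() else None)


def segmentation_threshold(stats: ReferenceStats, k_sd: float = DEFAULT_K_SD) -> float:
    """Threshold T = Mean_REF + k x SD_REF (k = 5 default, k = 4 selectable)."""
    if k_sd < 0:
        raise ValueError("k_sd must be >= 0")
    return stats.mean_ref + k_sd * stats.sd_ref


def cnr_map(mt_on: ImageVolume, stats: ReferenceStats, subject_id: str = "") -> CnrMap:
    """Voxelwise CNR = (V - Mean_REF)/SD_REF on the MT-on image."""
    values = (mt_on.values - stats.mean_ref) / stats.sd_ref
    if mt_on.missing is not None:
        values = np.where(mt_on.missing, np.nan, values)
    vol = ImageVolume(mt_on.grid, values, "cnr", missing=mt_on.missing)
    return CnrMap(vol, subject_id, stats.roi_name)


# ---------------------------------------------------------------------------
# Reference-region evaluation


@dataclass
class SubjectImages:
    """Per-subject inputs to the reference evaluation."""

    subject_id: str
    mt_on_avg: ImageVolume  # repeat-averaged MT-on (signal and SNR)
    mt_on_single: ImageVolume  # single repeat, paired with MT-off for MTR
    mt_off: ImageVolume


# Left/right families used by the asymmetry tests; midline candidates have none.
_LATERAL_FAMILY = {
    "left_pt": "pt",
    "right_pt": "pt",
    "left_scp": "scp",
    "right_scp": "scp",
}


@dataclass
class ReferenceEvaluation:
    """Outcome of the reference-region comparison across a cohort."""

    table: pd.DataFrame  # one row per subject x ROI: mean, sd, snr, mtr_mean
    asymmetry: pd.DataFrame  # one row per left/right pair: t, df, p
    selected: str
    decision: dict = field(default_factory=dict)


def evaluate_references(
    subjects: Sequence[SubjectImages],
    rois: dict[str, RoiMask],
    candidates: Iterable[str] = (
        "central_pt",
        "dorsal_pt",
        "left_pt",
        "right_pt",
        "left_scp",
        "right_scp",
    ),
    lc_areas: tuple[str, str] = ("lc_left", "lc_right"),
    alpha: float = 0.05,
) -> ReferenceEvaluation:
    """Rank candidate reference regions and test left/right signal asymmetry.

    Per subject and ROI the cohort table collects the mean signal, SD and SNR
    on the averaged MT-on image and the mean MTR (single MT-on vs MT-off).
    Paired two-sided t-tests compare left vs right mean signal for the
    pontine-tegmentum pair, the peduncle pair and the two nucleus searching
    areas. A candidate is suitable for bilateral use if its left/right family
    shows no significant asymmetry (midline candidates always pass); among
    suitable candidates the winner maximises cohort-mean SNR, with cohort-mean
    MTR as the tie-break — a region that is both quiet and strongly MT-
    suppressed gives the most sensitive threshold and CNR baseline.
    """
    candidates = list(candidates)
    if len(subjects) < 2:
        raise ConfigurationError("need >= 2 subjects for paired asymmetry tests")
    for name in list(candidates) + list(lc_areas):
        if name not in rois:
            raise ConfigurationError(f"missing ROI mask for {name!r}")

    rows = []
    for subj in subjects:
        mtr = mtr_map(subj.mt_off, subj.mt_on_single)
        for name in list(candidates) + list(lc_areas):
            st = region_stats(subj.mt_on_avg, rois[name], name)
            mtr_vals = region_values(mtr, rois[name])
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "roi": name,
                    "mean_signal": st.mean_ref,
                    "sd": st.sd_ref,
                    "snr": st.snr,
                    "mtr_mean": float(np.nanmean(mtr_vals)),
                    "n_voxels": st.n_voxels,
                }
            )
    table = pd.DataFrame(rows)

    def _paired(left: str, right: str, label: str) -> dict:
        lv = table.loc[table.roi == left].set_index("subject_id")["mean_signal"]
        rv = table.loc[table.roi == right].set_index("subject_id")["mean_signal"]
        lv, rv = lv.align(rv, join="inner")
        t, p = sps.ttest_rel(rv.values, lv.values)
        return {
            "pair": label,
            "left_roi": left,
            "right_roi": right,
            "t": float(t),
            "df": int(len(lv) - 1),
            "p": float(p),
            "right_minus_left": float(np.mean(rv.values - lv.values)),
        }

    asym_rows = [
        _paired("left_pt", "right_pt", "pt"),
        _paired("left_scp", "right_scp", "scp"),
        _paired(lc_areas[0], lc_areas[1], "lc"),
    ]
    asymmetry = pd.DataFrame(asym_rows).set_index("pair")

    cohort = (
        table[table.roi.isin(candidates)]
        .groupby("roi")[["mean_signal", "snr", "mtr_mean"]]
        .mean()
    )
    suitable = []
    for name in candidates:
        fam = _LATERAL_FAMILY.get(name)
        passes = fam is None or asymmetry.loc[fam, "p"] >= alpha
        suitable.append((name, bool(passes)))
    passing = [n for n, ok in suitable if ok]
    if not passing:
        raise ConfigurationError("no candidate reference passed the asymmetry gate")
    ranked = sorted(
        passing,
        key=lambda n: (cohort.loc[n, "snr"], cohort.loc[n, "mtr_mean"]),
        reverse=True,
    )
    selected = ranked[0]
    decision = {
        "selected": selected,
        "alpha": alpha,
        "ranking": ranked,
        "gate": {n: ok for n, ok in suitable},
        "cohort_means": cohort.round(6).to_dict(),
        "asymmetry": asymmetry.round(6).reset_index().to_dict(orient="records"),
        "rule": (
            "among candidates whose left/right family shows no significant "
            "signal asymmetry (paired t, two-sided), maximise cohort-mean SNR "
            "then cohort-mean MTR"
        ),
    }
    return ReferenceEvaluation(table, asymmetry, selected, decision)


def default_reference_specs(search_spec=None) -> list[ReferenceSpec]:
    """The six candidate reference regions on the default phantom layout.

    Midline/lateral pontine-tegmentum candidates are 4 x 4 x 4.5 mm cubes
    at mid-pons level (z = -22.5 mm); the peduncle candidates clone the
    searching-area geometry at the SCP roots.
    """
    from .rois import SearchSpec

    search_spec = search_spec or SearchSpec()
    z_mid = -22.5
    # central: pure tegmentum. dorsal: abuts the 4th-ventricle floor; lateral:
    # border the peduncles — both pick up mixed tissue, hence higher SD and
    # lower SNR, which is why the central cube wins the data-driven choice.
    specs = [
        ReferenceSpec("central_pt", "cube", (0.0, -5.0, z_mid)),
        ReferenceSpec("dorsal_pt", "cube", (0.0, -1.0, z_mid)),
        ReferenceSpec("left_pt", "cube", (-6.5, -4.0, z_mid)),
        ReferenceSpec("right_pt", "cube", (6.5, -4.0, z_mid)),
        ReferenceSpec(
            "left_scp", "lc_shaped", (-7.25, -1.25, z_mid), source=search_spec, hemisphere="left"
        ),
        ReferenceSpec(
            "right_scp", "lc_shaped", (7.25, -1.25, z_mid), source=search_spec, hemisphere="right"
        ),
    ]
    return specs


def build_reference_rois(grid, search_spec=None) -> dict[str, RoiMask]:
    """Rasterise the default candidates plus the two searching areas."""
    from .rois import SearchSpec, build_searching_areas

    search_spec = search_spec or SearchSpec()
    rois = {s.name: build_reference_roi(s, grid) for s in default_reference_specs(search_spec)}
    areas = build_searching_areas(search_spec, grid)
    rois["lc_left"] = areas["left"]
    rois["lc_right"] = areas["right"]
    return rois


__all__ = [
    "DEFAULT_K_SD",
    "ReferenceStats",
    "CnrMap",
    "SubjectImages",
    "ReferenceEvaluation",
    "region_values",
    "region_stats",
    "mtr_map",
    "segmentation_threshold",
    "cnr_map",
    "evaluate_references",
    "default_reference_specs",
    "build_reference_rois",
]
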