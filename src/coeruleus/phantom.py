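"""Synthetic MT phantom cohort with ground truth.

Each phantom subject is a pair of MT-on / MT-off volumes on a pons-sized
0.5 mm isotropic grid containing:

* a pontine background whose MT-on signal is suppressed by a configurable
  magnetisation-transfer ratio (MTR);
* two rod-shaped nuclei (one per hemisphere) with *lower* MTR than the
  surrounding tissue, hence hyperintense on MT-on — the contrast mechanism
  that makes the locus coeruleus visible on MT-weighted images;
* a bright midline stripe emulating the 4th ventricle (very low MTR), so
  the searching-area placement has something to avoid;
* rod-shaped superior-cerebellar-peduncle (SCP) regions with *higher* MTR
  (darker on MT-on), hosting the peduncle reference candidates.

The nuclei carry a rostrocaudal amplitude and radius gradient, per-subject
per-slice spatial jitter that grows toward the caudal end, and sub-voxel
partial-volume blending at the tube boundary computed from the exact
disc/voxel overlap area. Acquisition noise is additive Gaussian; the MT-on
scan is repeated ``n_repeats`` times (the MT-off once) and repeats are
averaged downstream to improve SNR.

The signal model is multiplicative MT suppression:
``mt_on = mt_off * (1 - MTR)`` per tissue, so the MTR map computed from a
noiseless pair recovers the configured tissue MTRs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import GenerationError
from .volumes import (
    DEFAULT_SLICE_CONVENTION,
    GridSpec,
    ImageVolume,
    RoiMask,
    SliceConvention,
    check_compatible,
    write_volume,
    write_mask,
)
from .rois import disc_coverage_fractions

# Default grid: 48 x 48 x 40 voxels at 0.5 mm isotropic; origin chosen so
# that no voxel centre sits at x == 0 (unambiguous hemispheres) and the
# axial slice numbering (112 <-> z = -16 mm) maps slices 86..112 onto grid
# z-indices 6..32.
DEFAULT_GRID = GridSpec(
    shape=(48, 48, 40),
    voxel_size_mm=(0.5, 0.5, 0.5),
    origin_mm=(-11.75, -11.75, -32.0),
)

Z_CAUDAL_MM = -29.0  # recess of the 4th ventricle (slice 86)
Z_ROSTRAL_MM = -16.0  # SCP decussation (slice 112)


@dataclass(frozen=True)
class PiecewiseLinear:
    """Piecewise-linear profile over the normalised rostrocaudal axis.

    ``points`` are (u, value) pairs with u in [0, 1]: u = 0 at the caudal
    boundary, u = 1 at the rostral boundary. Evaluation clamps outside
    [0, 1].
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        us = [p[0] for p in self.points]
        if len(us) < 1 or sorted(us) != us:
            raise ValueError("breakpoints must be sorted in u")

    def __call__(self, u: float | np.ndarray) -> float | np.ndarray:
        us = np.array([p[0] for p in self.points])
        vs = np.array([p[1] for p in self.points])
        return np.interp(u, us, vs)


@dataclass(frozen=True)
class Centerline:
    """Per-hemisphere tube centre (x, y) as a function of u (caudal->rostral)."""

    left: tuple[tuple[float, float, float], ...] = ((0.0, -4.25, -1.25), (1.0, -4.25, -1.25))
    right: tuple[tuple[float, float, float], ...] = ((0.0, 4.25, -1.25), (1.0, 4.25, -1.25))

    def xy(self, hemisphere: str, u: float) -> tuple[float, float]:
        pts = self.left if hemisphere == "left" else self.right
        us = np.array([p[0] for p in pts])
        xs = np.array([p[1] for p in pts])
        ys = np.array([p[2] for p in pts])
        return float(np.interp(u, us, xs)), float(np.interp(u, us, ys))


# Rostrocaudal profiles: radius and contrast peak centrally (u = 0.5, which
# lands on slice 99 / z = -22.5 mm), taper toward both ends with the caudal
# end weakest; jitter is largest caudally.
DEFAULT_RADIUS_PROFILE = PiecewiseLinear(((0.0, 0.6), (0.5, 1.25), (1.0, 0.6)))
DEFAULT_AMPLITUDE_PROFILE = PiecewiseLinear(((0.0, 0.55), (0.5, 1.0), (1.0, 0.75)))
DEFAULT_JITTER_PROFILE = PiecewiseLinear(((0.0, 0.6), (0.5, 0.25), (1.0, 0.25)))

DEFAULT_TISSUE_MTR = {"pons": 0.45, "scp": 0.55, "lc": 0.25, "ventricle": 0.02}
DEFAULT_MT_OFF_INTENSITY = {"pons": 1000.0, "scp": 1000.0, "lc": 1000.0, "ventricle": 800.0}

# Additive Gaussian noise SD: single-repeat pontine MT-on SNR
# = 1000 * (1 - 0.45) / 27.5 = 20.
DEFAULT_NOISE_SD = 27.5


@dataclass
class PhantomConfig:
    """Everything that defines a phantom cohort; fully serialisable."""

    n_subjects: int = 53
    grid: GridSpec = DEFAULT_GRID
    tissue_mtr: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_MTR))
    mt_off_intensity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MT_OFF_INTENSITY)
    )
    centerline: Centerline = field(default_factory=Centerline)
    radius_profile_mm: PiecewiseLinear = DEFAULT_RADIUS_PROFILE
    amplitude_profile: PiecewiseLinear = DEFAULT_AMPLITUDE_PROFILE
    jitter_sd_mm: PiecewiseLinear = DEFAULT_JITTER_PROFILE
    radial_droop: float = 0.3  # fractional intensity drop at the tube edge
    noise_sd: float = DEFAULT_NOISE_SD
    n_repeats: int = 3
    seed: int = 0
    age_range: tuple[int, int] = (52, 84)
    female_fraction: float = 24 / 53
    z_caudal_mm: float = Z_CAUDAL_MM
    z_rostral_mm: float = Z_ROSTRAL_MM
    right_intensity_bias: float = 1.0  # multiplies all signal at x > 0
    ablate_caudal_fraction: float = 0.0  # fraction of subjects with caudal half removed
    convention: SliceConvention = DEFAULT_SLICE_CONVENTION

    def __post_init__(self) -> None:
        for tissue, mtr in self.tissue_mtr.items():
            if not 0 <= mtr < 1:
                raise ValueError(f"MTR for {tissue} must be in [0, 1), got {mtr}")
        if self.tissue_mtr["lc"] >= self.tissue_mtr["pons"]:
            raise ValueError(
                "nucleus MTR must be below pons MTR (that inequality is what "
                "makes it hyperintense on MT-on)"
            )
        if self.n_subjects < 1 or self.n_repeats < 1:
            raise ValueError("n_subjects and n_repeats must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        us = np.linspace(0, 1, 101)
        if np.any(self.radius_profile_mm(us) <= 0) or np.any(self.amplitude_profile(us) <= 0):
            raise ValueError("radius and amplitude profiles must be strictly positive")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {
            "shape": list(self.grid.shape),
            "voxel_size_mm": list(self.grid.voxel_size_mm),
            "origin_mm": list(self.grid.origin_mm),
        }
        d["convention"] = asdict(self.convention)
        for key in ("radius_profile_mm", "amplitude_profile", "jitter_sd_mm"):
            d[key] = [list(p) for p in getattr(self, key).points]
        d["centerline"] = {
            "left": [list(p) for p in self.centerline.left],
            "right": [list(p) for p in self.centerline.right],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "grid" in d:
            g = d["grid"]
            d["grid"] = GridSpec(
                tuple(g["shape"]), tuple(g["voxel_size_mm"]), tuple(g["origin_mm"])
            )
        if "convention" in d:
            d["convention"] = SliceConvention(**d["convention"])
        for key in ("radius_profile_mm", "amplitude_profile", "jitter_sd_mm"):
            if key in d:
                d[key] = PiecewiseLinear(tuple(tuple(p) for p in d[key]))
        if "centerline" in d:
            c = d["centerline"]
            d["centerline"] = Centerline(
                tuple(tuple(p) for p in c["left"]), tuple(tuple(p) for p in c["right"])
            )
        for key in ("age_range",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SubjectTruth:
    """Ground truth for one phantom subject."""

    subject_id: str
    subject_index: int
    age: int
    sex: str  # 'F' or 'M'
    truth_masks: dict[str, RoiMask]  # per hemisphere
    pons_mask: RoiMask  # brainstem tissue (everything but the ventricle)
    true_centers: dict[str, dict[int, tuple[float, float]]]  # hemi -> slice -> (x, y) mm
    jitter: dict[str, dict[int, tuple[float, float]]]  # realised per-slice jitter (mm)
    amplitude: dict[int, float]  # slice -> contrast amplitude (0 where ablated)
    ablated: bool

    def truth_mask_combined(self) -> RoiMask:
        return self.truth_masks["left"].union(self.truth_masks["right"])


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Independent, reproducible per-subject stream."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))


def _tissue_fields(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless background MT-off and MT-on fields (no nuclei)."""
    grid = config.grid
    xs = grid.axis_coords_mm(0)[:, None, None]
    ys = grid.axis_coords_mm(1)[None, :, None]
    off = np.full(grid.shape, config.mt_off_intensity["pons"])
    mtr = np.full(grid.shape, config.tissue_mtr["pons"])

    # 4th-ventricle stripe: bright on MT-on (negligible MT effect), midline.
    vent = (np.abs(xs) <= 1.25) & (ys >= 0.5) & (ys <= 3.5)
    vent = np.broadcast_to(vent, grid.shape)
    off = np.where(vent, config.mt_off_intensity["ventricle"], off)
    mtr = np.where(vent, config.tissue_mtr["ventricle"], mtr)

    # SCP rods: strong MT effect (dark on MT-on), lateral to the nuclei.
    for sx in (-7.25, 7.25):
        scp = (xs - sx) ** 2 + (ys + 1.25) ** 2 <= 1.25**2 + 1e-9
        scp = np.broadcast_to(scp, grid.shape)
        off = np.where(scp, config.mt_off_intensity["scp"], off)
        mtr = np.where(scp, config.tissue_mtr["scp"], mtr)

    on = off * (1.0 - mtr)
    return off, on


def ventricle_mask(config: PhantomConfig) -> RoiMask:
    grid = config.grid
    xs = grid.axis_coords_mm(0)[:, None, None]
    ys = grid.axis_coords_mm(1)[None, :, None]
    vent = (np.abs(xs) <= 1.25) & (ys >= 0.5) & (ys <= 3.5)
    return RoiMask(grid, np.broadcast_to(vent, grid.shape).copy())


def _slab_grid_ks(config: PhantomConfig) -> np.ndarray:
    """Grid z-indices covered by the nucleus extent, caudal to rostral."""
    zs = config.grid.axis_coords_mm(2)
    ks = np.nonzero((zs >= config.z_caudal_mm - 1e-9) & (zs <= config.z_rostral_mm + 1e-9))[0]
    if ks.size == 0:
        raise GenerationError("configured z extent does not intersect the grid")
    return ks


def generate_subject(
    config: PhantomConfig, subject_index: int
) -> tuple[list[ImageVolume], list[ImageVolume], SubjectTruth]:
    """Generate one phantom subject.

    Returns (mt_off_repeats, mt_on_repeats, truth); a single MT-off repeat
    and ``config.n_repeats`` MT-on repeats. Deterministic given
    (config.seed, subject_index).
    """
    grid = config.grid
    rng = _subject_rng(config.seed, subject_index)
    off_bg, on_bg = _tissue_fields(config)

    base_off = config.mt_off_intensity["lc"]
    lc_on_full = base_off * (1.0 - config.tissue_mtr["lc"])
    pons_on = config.mt_off_intensity["pons"] * (1.0 - config.tissue_mtr["pons"])
    contrast_full = lc_on_full - pons_on

    n_ablate = int(round(config.ablate_caudal_fraction * config.n_subjects))
    ablated = subject_index < n_ablate
    z_span = config.z_rostral_mm - config.z_caudal_mm
    z_mid = config.z_caudal_mm + z_span / 2.0

    on = on_bg.copy()
    off = off_bg.copy()
    truth = {h: np.zeros(grid.shape, dtype=bool) for h in ("left", "right")}
    centers: dict[str, dict[int, tuple[float, float]]] = {"left": {}, "right": {}}
    jitters: dict[str, dict[int, tuple[float, float]]] = {"left": {}, "right": {}}
    amplitudes: dict[int, float] = {}

    zs = grid.axis_coords_mm(2)
    xs = grid.axis_coords_mm(0)
    ys = grid.axis_coords_mm(1)
    half_x = (xs[0] - grid.voxel_size_mm[0] / 2, xs[-1] + grid.voxel_size_mm[0] / 2)
    half_y = (ys[0] - grid.voxel_size_mm[1] / 2, ys[-1] + grid.voxel_size_mm[1] / 2)

    for k in _slab_grid_ks(config):
        z = zs[k]
        u = (z - config.z_caudal_mm) / z_span
        radius = float(config.radius_profile_mm(u))
        amp = float(config.amplitude_profile(u))
        jit_sd = float(config.jitter_sd_mm(u))
        slice_no = config.convention.z_to_slice(z)
        slice_ablated = ablated and z < z_mid
        amplitudes[slice_no] = 0.0 if slice_ablated else amp
        for hemi in ("left", "right"):
            x0, y0 = config.centerline.xy(hemi, u)
            jx, jy = rng.normal(0.0, jit_sd, size=2)
            cx, cy = x0 + jx, y0 + jy
            centers[hemi][slice_no] = (cx, cy)
            jitters[hemi][slice_no] = (float(jx), float(jy))
            if (
                cx - radius < half_x[0]
                or cx + radius > half_x[1]
                or cy - radius < half_y[0]
                or cy + radius > half_y[1]
            ):
                raise GenerationError(
                    f"subject {subject_index}: tube exits grid at slice {slice_no} "
                    f"(centre ({cx:.2f}, {cy:.2f}) mm, radius {radius:.2f} mm)"
                )
            if slice_ablated:
                continue
            ii, jj, frac = disc_coverage_fractions((cx, cy), radius, grid)
            if ii.size == 0:
                continue
            vx = xs[ii]
            vy = ys[jj]
            rho = np.sqrt((vx - cx) ** 2 + (vy - cy) ** 2)
            w = 1.0 - config.radial_droop * np.minimum(rho / radius, 1.0) ** 2
            # MT-off: tube shares the background baseline unless configured
            # otherwise; MT-on adds the partial-volume weighted contrast.
            off[ii, jj, k] += frac * (base_off - off_bg[ii, jj, k])
            on[ii, jj, k] += frac * amp * w * contrast_full
            truth[hemi][ii[frac >= 0.5], jj[frac >= 0.5], k] = True

    if config.right_intensity_bias != 1.0:
        bias = np.where(xs[:, None, None] > 0, config.right_intensity_bias, 1.0)
        on = on * bias
        off = off * bias

    mt_off_repeats = [
        ImageVolume(grid, off + rng.normal(0.0, config.noise_sd, grid.shape), "mt_off")
        if config.noise_sd > 0
        else ImageVolume(grid, off.copy(), "mt_off")
    ]
    mt_on_repeats = []
    for _ in range(config.n_repeats):
        noisy = on + rng.normal(0.0, config.noise_sd, grid.shape) if config.noise_sd > 0 else on.copy()
        mt_on_repeats.append(ImageVolume(grid, noisy, "mt_on"))

    sex = "F" if rng.random() < config.female_fraction else "M"
    age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
    pons = RoiMask(grid, ~ventricle_mask(config).data)
    truth_obj = SubjectTruth(
        subject_id=f"sub-{subject_index:03d}",
        subject_index=subject_index,
        age=age,
        sex=sex,
        truth_masks={h: RoiMask(grid, truth[h]) for h in ("left", "right")},
        pons_mask=pons,
        true_centers=centers,
        jitter=jitters,
        amplitude=amplitudes,
        ablated=ablated,
    )
    return mt_off_repeats, mt_on_repeats, truth_obj


def average_repeats(repeats: Sequence[ImageVolume]) -> ImageVolume:
    """Voxelwise arithmetic mean of grid-compatible, already-aligned repeats."""
    if len(repeats) == 0:
        raise ValueError("need at least one repeat")
    check_compatible(*repeats)
    mean = np.mean([r.values for r in repeats], axis=0)
    return ImageVolume(repeats[0].grid, mean, repeats[0].modality)


def generate_cohort(
    config: PhantomConfig, out_dir: str | Path | None = None
) -> tuple[list[SubjectTruth], pd.DataFrame]:
    """Generate the whole cohort; optionally write NIfTI volumes and a TSV table.

    When ``out_dir`` is given, writes per subject ``n_repeats`` MT-on volumes
    (total n_subjects x n_repeats MT-on scans), one MT-off volume, the
    ground-truth masks, plus ``cohort.tsv`` and ``phantom_config.yaml``.
    """
    truths: list[SubjectTruth] = []
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for idx in range(config.n_subjects):
        mt_off, mt_on, truth = generate_subject(config, idx)
        truths.append(truth)
        rows.append(
            {
                "subject_id": truth.subject_id,
                "age": truth.age,
                "sex": truth.sex,
                "seed": config.seed,
                "subject_index": idx,
                "ablated": truth.ablated,
            }
        )
        if out is not None:
            write_volume(mt_off[0], out / f"{truth.subject_id}_mt-off.nii.gz")
            for r, vol in enumerate(mt_on):
                write_volume(vol, out / f"{truth.subject_id}_mt-on_rep-{r + 1}.nii.gz")
            for hemi in ("left", "right"):
                write_mask(
                    truth.truth_masks[hemi], out / f"{truth.subject_id}_truth-{hemi}.nii.gz"
                )
    table = pd.DataFrame(rows)
    if out is not None:
        table.to_csv(out / "cohort.tsv", sep="\t", index=False)
        config.to_yaml(out / "phantom_config.yaml")
    return truths, table


def noiseless_config(config: PhantomConfig, flat_profiles: bool = False) -> PhantomConfig:
    """Copy of a config with noise and jitter removed (and optionally flat
    amplitude/radius profiles), for closed-form checks."""
    d = config.to_dict()
    d["noise_sd"] = 0.0
    d["jitter_sd_mm"] = [[0.0, 0.0], [1.0, 0.0]]
    if flat_profiles:
        d["amplitude_profile"] = [[0.0, 1.0], [1.0, 1.0]]
        d["radial_droop"] = 0.0
    return PhantomConfig.from_dict(d)


__all__ = [
    "DEFAULT_GRID",
    "PhantomConfig",
    "SubjectTruth",
    "PiecewiseLinear",
    "Centerline",
    "generate_subject",
    "generate_cohort",
    "average_repeats",
    "ventricle_mask",
    "noiseless_config",
]
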