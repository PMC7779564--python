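"""ROI geometry: searching areas, reference regions, disc rasterisation, Dice.

The nucleus searching area is a stack of circular discs (one per axial
slice) following a per-slice centre path; candidate reference regions are
either axis-aligned cubes in the pontine tegmentum or clones of the
searching-area geometry translated to the superior cerebellar peduncles.

Membership rules (deliberate conventions, stated once here):

* disc: a voxel belongs to a disc iff its *centre* lies within Euclidean
  distance <= diameter/2 of the disc centre (closed disc). At 0.5 mm
  isotropic resolution a 2.5 mm disc centred on a voxel centre covers
  exactly 21 voxels, so a 27-slice stack covers 567 voxels = 70.875 mm^3.
* cube: voxel centre within the closed axis-aligned box (small tolerance
  for float round-off).
* hemispheres: world x < 0 is left, x > 0 is right; voxels at exactly
  x = 0 belong to neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .exceptions import EmptyMaskError, UndefinedDiceError
from .volumes import (
    DEFAULT_SLICE_CONVENTION,
    GridSpec,
    RoiMask,
    SliceConvention,
    check_compatible,
    grid_k_for_slice,
)

_TOL = 1e-9

Hemisphere = Literal["left", "right"]
HEMISPHERES: tuple[Hemisphere, Hemisphere] = ("left", "right")

# Default slab: rostral boundary at the decussation of the superior
# cerebellar peduncles (slice 112, z=-16 mm), caudal boundary at the recess
# of the 4th ventricle (slice 86, z=-29 mm): 27 slices spanning 13.5 mm.
DEFAULT_ROSTRAL_SLICE = 112
DEFAULT_CAUDAL_SLICE = 86
DEFAULT_DISC_DIAMETER_MM = 2.5

# Default centre path: bilateral tubes in the dorsal pons, mirrored about
# the midline; chosen to sit on voxel centres of the default phantom grid.
DEFAULT_CENTERS_XY: dict[Hemisphere, tuple[float, float]] = {
    "left": (-4.25, -1.25),
    "right": (4.25, -1.25),
}


# ---------------------------------------------------------------------------
# Exact disc / rectangle overlap (used for partial-volume fractions)


def _antideriv(t: float, r: float) -> float:
    """Antiderivative of sqrt(r^2 - x^2), clipped to the disc support."""
    t = min(max(t, -r), r)
    return 0.5 * (t * math.sqrt(max(r * r - t * t, 0.0)) + r * r * math.asin(t / r))


def _strip_integral(a: float, b: float, r: float) -> float:
    """Integral of the half-chord sqrt(r^2 - x^2) over [a, b]."""
    return _antideriv(b, r) - _antideriv(a, r)


def _clipped_chord_integral(y: float, x0: float, x1: float, r: float) -> float:
    """Integral over x in [x0, x1] of clip(y, -s(x), s(x)) with s = sqrt(r^2-x^2)."""
    if y == 0.0:
        return 0.0
    c = math.sqrt(max(r * r - y * y, 0.0))
    lo = min(max(x0, -c), c)
    hi = min(max(x1, -c), c)
    inner = y * (hi - lo)
    outer = _strip_integral(x0, x1, r) - _strip_integral(lo, hi, r)
    return inner + math.copysign(outer, y)


def disc_rect_overlap_area(
    cx: float, cy: float, r: float, x0: float, x1: float, y0: float, y1: float
) -> float:
    """Exact area of the intersection of a disc with an axis-aligned rectangle.

    The disc has centre (cx, cy) and radius r; the rectangle is
    [x0, x1] x [y0, y1]. Closed form via the integral of the clipped chord.
    """
    if r <= 0.0 or x1 <= x0 or y1 <= y0:
        return 0.0
    a, b = x0 - cx, x1 - cx
    top = _clipped_chord_integral(y1 - cy, a, b, r)
    bot = _clipped_chord_integral(y0 - cy, a, b, r)
    return max(top - bot, 0.0)


def disc_coverage_fractions(
    center_xy: tuple[float, float],
    radius_mm: float,
    grid: GridSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-plane partial-volume fractions of a disc over the voxel lattice.

    Returns (ii, jj, frac): x/y voxel indices touching the disc and the
    fraction of each voxel's in-plane footprint covered (0 < frac <= 1).
    """
    sx, sy, _ = grid.voxel_size_mm
    ox, oy, _ = grid.origin_mm
    cx, cy = center_xy
    i_lo = max(0, math.floor((cx - radius_mm - ox) / sx - 0.5))
    i_hi = min(grid.shape[0] - 1, math.ceil((cx + radius_mm - ox) / sx + 0.5))
    j_lo = max(0, math.floor((cy - radius_mm - oy) / sy - 0.5))
    j_hi = min(grid.shape[1] - 1, math.ceil((cy + radius_mm - oy) / sy + 0.5))
    ii, jj, fr = [], [], []
    cell = sx * sy
    for i in range(int(i_lo), int(i_hi) + 1):
        xc = ox + i * sx
        for j in range(int(j_lo), int(j_hi) + 1):
            yc = oy + j * sy
            area = disc_rect_overlap_area(
                cx, cy, radius_mm, xc - sx / 2, xc + sx / 2, yc - sy / 2, yc + sy / 2
            )
            if area > 0.0:
                ii.append(i)
                jj.append(j)
                fr.append(area / cell)
    return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int), np.asarray(fr)


# ---------------------------------------------------------------------------
# Disc rasterisation and searching areas


def rasterize_disc(
    center_xy: tuple[float, float],
    diameter_mm: float,
    grid: GridSpec,
    slice_index: int,
    convention: SliceConvention | None = None,
) -> RoiMask:
    """Binary disc on one axial slice by the centre-within-radius rule.

    ``slice_index`` is the grid z-index, or an axial slice number if a
    :class:`SliceConvention` is given. Raises :class:`EmptyMaskError` if the
    disc covers no voxel centre.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    k = grid_k_for_slice(slice_index, grid, convention) if convention else int(slice_index)
    if not 0 <= k < grid.shape[2]:
        raise EmptyMaskError(f"slice {slice_index} outside grid")
    xs = grid.axis_coords_mm(0)
    ys = grid.axis_coords_mm(1)
    dx = xs[:, None] - center_xy[0]
    dy = ys[None, :] - center_xy[1]
    inside = dx * dx + dy * dy <= (diameter_mm / 2) ** 2 + _TOL
    if not inside.any():
        raise EmptyMaskError(
            f"disc at {center_xy} (diameter {diameter_mm} mm) covers no voxel centre"
        )
    data = np.zeros(grid.shape, dtype=bool)
    data[:, :, k] = inside
    return RoiMask(grid, data)


CenterPath = Callable[[Hemisphere, int], tuple[float, float]]


def constant_center_path(
    centers_xy: dict[Hemisphere, tuple[float, float]] = DEFAULT_CENTERS_XY,
) -> CenterPath:
    """Centre path that is constant across slices (straight vertical tubes)."""

    def path(hemisphere: Hemisphere, slice_index: int) -> tuple[float, float]:
        return centers_xy[hemisphere]

    return path


@dataclass
class SearchSpec:
    """Geometry of the bilateral searching areas.

    ``center_path`` maps (hemisphere, axial slice number) to the disc centre
    (x, y) in mm. Axial slice numbers follow ``convention``; the slab runs
    from ``caudal_slice`` to ``rostral_slice`` inclusive.
    """

    diameter_mm: float = DEFAULT_DISC_DIAMETER_MM
    rostral_slice: int = DEFAULT_ROSTRAL_SLICE
    caudal_slice: int = DEFAULT_CAUDAL_SLICE
    center_path: CenterPath = field(default_factory=constant_center_path)
    convention: SliceConvention = DEFAULT_SLICE_CONVENTION

    def __post_init__(self) -> None:
        if self.rostral_slice < self.caudal_slice:
            raise ValueError("rostral slice must not precede caudal slice")
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")

    @property
    def slices(self) -> range:
        return range(self.caudal_slice, self.rostral_slice + 1)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def extent_mm(self) -> float:
        """Rostrocaudal extent of the slab: slice count times slice thickness."""
        return self.n_slices * self.convention.dz_mm


def build_searching_area(
    spec: SearchSpec, grid: GridSpec, hemisphere: Hemisphere
) -> RoiMask:
    """Union of per-slice discs along the centre path for one hemisphere."""
    data = np.zeros(grid.shape, dtype=bool)
    for s in spec.slices:
        center = spec.center_path(hemisphere, s)
        disc = rasterize_disc(center, spec.diameter_mm, grid, s, spec.convention)
        data |= disc.data
    return RoiMask(grid, data)


def build_searching_areas(spec: SearchSpec, grid: GridSpec) -> dict[Hemisphere, RoiMask]:
    return {h: build_searching_area(spec, grid, h) for h in HEMISPHERES}


# ---------------------------------------------------------------------------
# Reference ROIs

ReferenceName = Literal[
    "central_pt", "dorsal_pt", "left_pt", "right_pt", "left_scp", "right_scp"
]

DEFAULT_CUBE_SIZE_MM = (4.0, 4.0, 4.5)


@dataclass
class ReferenceSpec:
    """A candidate reference region.

    ``shape == 'cube'``: axis-aligned box of ``size_mm`` centred at
    ``center_mm`` (the pontine-tegmentum candidates; default 4 x 4 x 4.5 mm
    = 72 mm^3). ``shape == 'lc_shaped'``: a clone of ``source`` searching
    geometry whose centre path is shifted so the named hemisphere's path
    passes through ``center_mm`` in-plane (the peduncle candidates).
    """

    name: str
    shape: Literal["cube", "lc_shaped"] = "cube"
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    size_mm: tuple[float, float, float] = DEFAULT_CUBE_SIZE_MM
    source: SearchSpec | None = None
    hemisphere: Hemisphere = "left"


def build_reference_roi(spec: ReferenceSpec, grid: GridSpec) -> RoiMask:
    """Rasterise a reference ROI; raises :class:`EmptyMaskError` if off-grid."""
    if spec.shape == "cube":
        half = np.asarray(spec.size_mm) / 2.0
        center = np.asarray(spec.center_mm)
        data = np.ones(grid.shape, dtype=bool)
        for axis in range(3):
            coords = grid.axis_coords_mm(axis)
            ok = np.abs(coords - center[axis]) <= half[axis] + _TOL
            shape = [1, 1, 1]
            shape[axis] = -1
            data &= ok.reshape(shape)
        mask = RoiMask(grid, data)
        if mask.is_empty:
            raise EmptyMaskError(f"cube reference '{spec.name}' covers no voxel centre")
        lo = center - half - _TOL
        hi = center + half + _TOL
        for axis in range(3):
            coords = grid.axis_coords_mm(axis)
            if lo[axis] < coords[0] - grid.voxel_size_mm[axis] / 2 or hi[axis] > coords[
                -1
            ] + grid.voxel_size_mm[axis] / 2:
                raise EmptyMaskError(
                    f"cube reference '{spec.name}' exceeds the grid on axis {axis}"
                )
        return mask
    if spec.shape == "lc_shaped":
        if spec.source is None:
            raise ValueError("lc_shaped reference requires a source SearchSpec")
        src = spec.source
        base_xy = src.center_path(spec.hemisphere, src.rostral_slice)
        shift = (spec.center_mm[0] - base_xy[0], spec.center_mm[1] - base_xy[1])

        def shifted(h: Hemisphere, s: int, _orig=src.center_path) -> tuple[float, float]:
            x, y = _orig(spec.hemisphere, s)
            return (x + shift[0], y + shift[1])

        clone = SearchSpec(
            diameter_mm=src.diameter_mm,
            rostral_slice=src.rostral_slice,
            caudal_slice=src.caudal_slice,
            center_path=shifted,
            convention=src.convention,
        )
        return build_searching_area(clone, grid, spec.hemisphere)
    raise ValueError(f"unknown reference shape {spec.shape!r}")


# ---------------------------------------------------------------------------
# Dice similarity


def dice(a: RoiMask, b: RoiMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) between two masks."""
    check_compatible(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise UndefinedDiceError("Dice undefined: both masks empty")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def hemisphere_split(mask: RoiMask) -> dict[Hemisphere, RoiMask]:
    """Split a mask at the midline: x < 0 left, x > 0 right, x == 0 dropped."""
    xs = mask.grid.axis_coords_mm(0)
    left = mask.data & (xs < -_TOL)[:, None, None]
    right = mask.data & (xs > _TOL)[:, None, None]
    return {"left": RoiMask(mask.grid, left), "right": RoiMask(mask.grid, right)}


__all__ = [
    "HEMISPHERES",
    "Hemisphere",
    "SearchSpec",
    "ReferenceSpec",
    "CenterPath",
    "constant_center_path",
    "DEFAULT_CENTERS_XY",
    "DEFAULT_DISC_DIAMETER_MM",
    "DEFAULT_ROSTRAL_SLICE",
    "DEFAULT_CAUDAL_SLICE",
    "DEFAULT_CUBE_SIZE_MM",
    "disc_rect_overlap_area",
    "disc_coverage_fractions",
    "rasterize_disc",
    "build_searching_area",
    "build_searching_areas",
    "build_reference_roi",
    "dice",
    "hemisphere_split",
]
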