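"""Volume and mask data model, NIfTI I/O and grid conventions.

All stages of the pipeline operate on scalar volumes and binary masks that
live on a common axis-aligned regular grid. World coordinates follow the
usual neuroimaging convention: x runs left -> right, y posterior -> anterior,
z inferior -> superior, and every coordinate refers to a voxel *centre*.
Only axis-aligned grids are supported: the volumes consumed here are assumed
to be already normalised to a standard space, so no rotation is required.

Axial slice numbering is tied to world z by a configurable anchor; the
default convention places slice 112 at z = -16 mm with 0.5 mm spacing
(slice index decreasing toward the caudal end), so slice 86 sits at
z = -29 mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import nibabel as nib
import numpy as np

from .exceptions import (
    EmptyMaskError,
    GridCompatibilityError,
    SliceRangeError,
    UnsupportedGeometryError,
)

Modality = Literal["mt_on", "mt_off", "mtr", "cnr", "prob", "other"]

_AFFINE_TOL = 1e-3


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned regular 3-D grid.

    ``origin_mm`` is the world coordinate of the centre of voxel (0, 0, 0);
    world = origin + index * voxel_size, elementwise.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three entries >= 1, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.voxel_size_mm
        return sx * sy * sz

    def voxel_to_world(self, index: Sequence[float]) -> np.ndarray:
        """World coordinate (mm) of a voxel centre; accepts fractional indices."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(
            self.voxel_size_mm
        )

    def world_to_voxel(self, xyz_mm: Sequence[float]) -> np.ndarray:
        """Fractional voxel index of a world coordinate."""
        return (np.asarray(xyz_mm, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(
            self.voxel_size_mm
        )

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Voxel-centre world coordinates along one axis (0=x, 1=y, 2=z)."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.voxel_size_mm[axis]

    def contains_index(self, index: Sequence[int]) -> bool:
        return all(0 <= int(i) < s for i, s in zip(index, self.shape))

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff


def _check_compatible(a: GridSpec, b: GridSpec) -> None:
    if a != b:
        raise GridCompatibilityError(f"grids differ: {a} vs {b}")


@dataclass
class ImageVolume:
    """3-D scalar field on a :class:`GridSpec` with a modality tag.

    ``missing`` optionally flags voxels whose value is undefined (e.g. MTR at
    near-zero MT-off signal); flagged voxels hold NaN in ``values``.
    """

    grid: GridSpec
    values: np.ndarray
    modality: Modality = "other"
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.grid.shape:
                raise ValueError("missing-mask shape mismatch")
            bad = ~np.isfinite(self.values) & ~self.missing
        else:
            bad = ~np.isfinite(self.values)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} non-finite voxels not flagged missing")

    def compatible_with(self, other: "ImageVolume | RoiMask") -> bool:
        return self.grid == other.grid

    def copy(self, **updates) -> "ImageVolume":
        fields = {
            "grid": self.grid,
            "values": self.values.copy(),
            "modality": self.modality,
            "missing": None if self.missing is None else self.missing.copy(),
        }
        fields.update(updates)
        return ImageVolume(**fields)


@dataclass
class RoiMask:
    """Binary voxel set on a :class:`GridSpec`."""

    grid: GridSpec
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(f"mask shape {self.data.shape} != grid shape {self.grid.shape}")

    @classmethod
    def from_indices(cls, grid: GridSpec, indices: Iterable[Sequence[int]]) -> "RoiMask":
        data = np.zeros(grid.shape, dtype=bool)
        for idx in indices:
            data[tuple(int(i) for i in idx)] = True
        return cls(grid, data)

    @classmethod
    def empty(cls, grid: GridSpec) -> "RoiMask":
        return cls(grid, np.zeros(grid.shape, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of member voxels, in scan order."""
        return np.argwhere(self.data)

    def union(self, other: "RoiMask") -> "RoiMask":
        _check_compatible(self.grid, other.grid)
        return RoiMask(self.grid, self.data | other.data)

    def intersection(self, other: "RoiMask") -> "RoiMask":
        _check_compatible(self.grid, other.grid)
        return RoiMask(self.grid, self.data & other.data)

    def difference(self, other: "RoiMask") -> "RoiMask":
        _check_compatible(self.grid, other.grid)
        return RoiMask(self.grid, self.data & ~other.data)


def mask_volume_mm3(mask: RoiMask) -> float:
    """Physical mask volume: voxel count times voxel volume (0 for empty masks)."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> GridSpec:
    rot = affine[:3, :3]
    offdiag = rot - np.diag(np.diag(rot))
    if np.abs(offdiag).max() > _AFFINE_TOL:
        raise UnsupportedGeometryError(
            "affine has off-diagonal terms above tolerance; only axis-aligned "
            f"grids are supported (max |off-diagonal| = {np.abs(offdiag).max():.3g})"
        )
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise UnsupportedGeometryError(
            f"affine diagonal must be positive (RAS+ voxel sizes), got {diag}"
        )
    # headers carry float32: snap to 1e-6 mm so grids round-trip exactly
    return GridSpec(
        shape=tuple(int(s) for s in shape[:3]),
        voxel_size_mm=tuple(float(np.round(d, 6)) for d in diag),
        origin_mm=tuple(float(np.round(t, 6)) for t in affine[:3, 3]),
    )


def read_volume(path: str | Path, modality: Modality = "other") -> ImageVolume:
    """Read a NIfTI-1 volume into an :class:`ImageVolume`.

    The grid is derived from the header affine, which must be axis-aligned
    (off-diagonal terms below 1e-3) with positive diagonal; voxel sizes are
    taken in mm. NaN voxels are flagged missing.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except UnsupportedGeometryError:
        raise
    except Exception as exc:  # nibabel raises a mix of IOError subclasses
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise IOError(f"expected a 3-D volume at {path}, got shape {data.shape}")
    grid = _grid_from_affine(np.asarray(img.affine), data.shape)
    missing = ~np.isfinite(data)
    return ImageVolume(
        grid=grid,
        values=np.where(missing, np.nan, data),
        modality=modality,
        missing=missing if missing.any() else None,
    )


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as float32 NIfTI-1 (missing voxels stored as NaN)."""
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.grid.affine())
    nib.save(img, str(path))


def read_mask(path: str | Path) -> RoiMask:
    """Read a binary mask stored as a {0,1} NIfTI volume."""
    vol = read_volume(path)
    return RoiMask(vol.grid, vol.values > 0.5)


def write_mask(mask: RoiMask, path: str | Path) -> None:
    """Write a mask as uint8 {0,1} NIfTI-1."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Axial slice numbering


@dataclass(frozen=True)
class SliceConvention:
    """Anchored linear map between axial slice numbers and world z (mm).

    Defaults anchor slice 112 at z = -16 mm with 0.5 mm spacing, placing
    slice 86 at z = -29 mm (the caudal boundary of the search slab).
    """

    anchor_slice: int = 112
    anchor_z_mm: float = -16.0
    dz_mm: float = 0.5

    def slice_to_z(self, slice_index: int) -> float:
        return self.anchor_z_mm + self.dz_mm * (slice_index - self.anchor_slice)

    def z_to_slice(self, z_mm: float) -> int:
        frac = (z_mm - self.anchor_z_mm) / self.dz_mm + self.anchor_slice
        k = round(frac)
        if abs(frac - k) > 1e-6:
            raise ValueError(f"z = {z_mm} mm is not on the slice grid (got index {frac})")
        return int(k)


DEFAULT_SLICE_CONVENTION = SliceConvention()


def slice_to_z(
    slice_index: int,
    grid: GridSpec | None = None,
    convention: SliceConvention = DEFAULT_SLICE_CONVENTION,
) -> float:
    """World z (mm) of an axial slice number; errors if it lies outside ``grid``."""
    z = convention.slice_to_z(slice_index)
    if grid is not None:
        zs = grid.axis_coords_mm(2)
        if z < zs[0] - 1e-9 or z > zs[-1] + 1e-9:
            raise SliceRangeError(
                f"slice {slice_index} (z = {z} mm) outside grid z range "
                f"[{zs[0]}, {zs[-1]}] mm"
            )
    return z


def z_to_slice(
    z_mm: float,
    grid: GridSpec | None = None,
    convention: SliceConvention = DEFAULT_SLICE_CONVENTION,
) -> int:
    """Inverse of :func:`slice_to_z`; exact for on-grid z."""
    k = convention.z_to_slice(z_mm)
    if grid is not None:
        slice_to_z(k, grid, convention)  # range check
    return k


def grid_k_for_slice(
    slice_index: int,
    grid: GridSpec,
    convention: SliceConvention = DEFAULT_SLICE_CONVENTION,
) -> int:
    """Grid z-index (third array axis) of an axial slice number."""
    z = slice_to_z(slice_index, grid, convention)
    frac = (z - grid.origin_mm[2]) / grid.voxel_size_mm[2]
    k = round(frac)
    if abs(frac - k) > 1e-6:
        raise SliceRangeError(
            f"slice {slice_index} (z = {z} mm) does not sit on a voxel centre"
        )
    return int(k)


def slice_for_grid_k(
    k: int,
    grid: GridSpec,
    convention: SliceConvention = DEFAULT_SLICE_CONVENTION,
) -> int:
    """Axial slice number of grid z-index ``k``."""
    if not 0 <= k < grid.shape[2]:
        raise SliceRangeError(f"grid z-index {k} outside shape {grid.shape}")
    z = grid.origin_mm[2] + k * grid.voxel_size_mm[2]
    return convention.z_to_slice(z)


def require_nonempty(mask: RoiMask, what: str = "mask") -> RoiMask:
    if mask.is_empty:
        raise EmptyMaskError(f"{what} is empty")
    return mask


def check_compatible(*objs: ImageVolume | RoiMask) -> None:
    """Raise unless all volumes/masks share one grid."""
    grids = {o.grid for o in objs}
    if len(grids) > 1:
        raise GridCompatibilityError(f"incompatible grids: {grids}")


__all__ = [
    "GridSpec",
    "ImageVolume",
    "RoiMask",
    "SliceConvention",
    "DEFAULT_SLICE_CONVENTION",
    "mask_volume_mm3",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "slice_to_z",
    "z_to_slice",
    "grid_k_for_slice",
    "slice_for_grid_k",
    "require_nonempty",
    "check_compatible",
]
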