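"""NIfTI-1 I/O, voxel-grid bookkeeping, and group-mask construction.

All images participating in one analysis must live on a single voxel grid
(same shape, same affine): the pipeline never resamples, so a grid mismatch
is always raised as an error rather than silently interpolated away.
World (scanner/MNI) coordinates are in millimetres via the affine; voxel
indices are 0-based and internal only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "TimeSeriesImage",
    "ScalarMap",
    "BrainMask",
    "GridMismatchError",
    "read_timeseries",
    "read_map",
    "read_mask",
    "write_timeseries",
    "write_map",
    "write_mask",
    "intersect_masks",
]

#: admissible labels for :class:`ScalarMap.kind`
MAP_KINDS = ("alff", "malff", "gm", "tstat", "pvalue", "effect")

AFFINE_ATOL_MM = 1e-4


class GridMismatchError(ValueError):
    """Two images that must share a voxel grid do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with its voxel-to-world (mm) affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be positive along every axis")

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of a voxel along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if out.shape[0] == 1 and np.asarray(ijk).ndim == 2 else out

    def matches(self, other: "VoxelGrid", atol: float = AFFINE_ATOL_MM) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float = 3.0) -> "VoxelGrid":
        """A centred RAS+ grid with cubic voxels, handy for simulation."""
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        aff[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
        return cls(tuple(shape), aff)


def _require_same_grid(a: VoxelGrid, b: VoxelGrid, what: str) -> None:
    if not a.matches(b):
        raise GridMismatchError(
            f"{what}: grids differ (shapes {a.shape} vs {b.shape}, "
            f"max affine deviation "
            f"{np.max(np.abs(a.affine - b.affine)) if a.shape == b.shape else 'n/a'})"
        )


@dataclass
class TimeSeriesImage:
    """One subject's 4D BOLD-like image with its repetition time (s)."""

    grid: VoxelGrid
    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        # float32 series (e.g. simulated cohorts) are kept as-is to halve
        # memory traffic; anything else is promoted to float64
        self.data = np.asarray(self.data)
        if self.data.dtype != np.float32:
            self.data = self.data.astype(np.float64, copy=False)
        if self.data.ndim != 4:
            raise ValueError(f"not a 4D image (got {self.data.ndim} dimensions)")
        if self.data.shape[:3] != self.grid.shape:
            raise GridMismatchError(
                f"data shape {self.data.shape[:3]} does not match grid {self.grid.shape}"
            )
        if self.n_volumes < 8:
            raise ValueError(f"need at least 8 volumes for a spectrum, got {self.n_volumes}")
        if not (self.tr > 0):
            raise ValueError(f"repetition time must be positive, got {self.tr}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class ScalarMap:
    """A 3D voxelwise map (ALFF, standardized ALFF, GM volume, t, p, ...)."""

    grid: VoxelGrid
    data: np.ndarray
    kind: str = "effect"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {MAP_KINDS}")
        if self.data.shape != self.grid.shape:
            raise GridMismatchError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )


@dataclass
class BrainMask:
    """Boolean inclusion map: the voxels that take part in the analysis."""

    grid: VoxelGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if self.n_voxels < 1:
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# NIfTI round trips


def _load(path: os.PathLike | str) -> nib.Nifti1Image:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return nib.load(str(path))


def _grid_of(img: nib.Nifti1Image) -> VoxelGrid:
    return VoxelGrid(tuple(img.shape[:3]), np.asarray(img.affine, dtype=float))


def read_timeseries(path: os.PathLike | str, tr: float | None = None) -> TimeSeriesImage:
    """Read a 4D NIfTI-1 file.

    The repetition time is taken from the header (``pixdim[4]``) unless an
    explicit ``tr`` is supplied; an explicit value always wins because
    headers are wrong often enough in the wild.
    """
    img = _load(path)
    if img.ndim != 4:
        raise ValueError(f"{path}: not a 4D image (got {img.ndim} dimensions)")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr > 0:
            raise ValueError(
                f"{path}: header has no positive TR and no override was supplied"
            )
    data = np.asarray(img.dataobj, dtype=np.float64)
    return TimeSeriesImage(_grid_of(img), data, float(tr))


def read_map(path: os.PathLike | str, kind: str = "effect") -> ScalarMap:
    img = _load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: not a 3D image (got {img.ndim} dimensions)")
    return ScalarMap(_grid_of(img), np.asarray(img.dataobj, dtype=np.float64), kind)


def read_mask(path: os.PathLike | str) -> BrainMask:
    img = _load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: not a 3D image (got {img.ndim} dimensions)")
    return BrainMask(_grid_of(img), np.asarray(img.dataobj) > 0)


def _check_writable(path: os.PathLike | str) -> None:
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")


def write_timeseries(ts: TimeSeriesImage, path: os.PathLike | str) -> None:
    _check_writable(path)
    img = nib.Nifti1Image(ts.data, ts.grid.affine)
    img.header.set_zooms((*ts.grid.voxel_size, ts.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_map(m: ScalarMap, path: os.PathLike | str) -> None:
    """Write a scalar map as float64 NIfTI-1 (values round-trip bit-exactly)."""
    _check_writable(path)
    img = nib.Nifti1Image(m.data.astype(np.float64), m.grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def write_mask(mask: BrainMask, path: os.PathLike | str) -> None:
    _check_writable(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Group mask


def intersect_masks(masks: list[BrainMask]) -> BrainMask:
    """Voxels inside the brain of *every* subject simultaneously.

    This intersection is the analysis domain for ALFF standardization and
    for the group statistics. An empty intersection is an error, never a
    silently empty mask.
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask to intersect")
    grid = masks[0].grid
    out = np.ones(grid.shape, dtype=bool)
    for i, m in enumerate(masks):
        _require_same_grid(grid, m.grid, f"intersect_masks (mask {i})")
        out &= m.data
    if not out.any():
        raise ValueError("empty intersection: no voxel is inside every mask")
    return BrainMask(grid, out)
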