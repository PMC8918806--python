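"""Domain types and I/O shared by every pipeline stage.

Volumes are 3D scalar fields indexed ``(z, y, x)`` with explicit per-axis
physical spacing in micrometres.  Indexing is 0-based with half-open bounds;
the physical coordinate of a voxel centre is ``index * spacing``.  Masks use
the convention foreground (vessel) = 1; an ``inverted`` flag on mask I/O
writes/reads the 0=vessel, 255=background images some Fiji pipelines expect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "ROIBox",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_landmarks",
    "write_landmarks",
    "read_roi",
    "write_roi",
    "read_transform_matrix",
    "write_transform_matrix",
    "downsample_xy",
    "crop_to_roi",
    "max_intensity_projection",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """A 3D scalar field with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities; must be finite.
    spacing : tuple of float
        Physical voxel size ``(sz, sy, sx)`` in µm, all > 0.
    dtype_range : tuple of float, optional
        Intensity dynamic range ``(lo, hi)``; defaults to the dtype limits
        for integer data and the data min/max for floats.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    dtype_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 and self.data.ndim != 3:
            raise ValueError(f"expected 3D array, got ndim={self.data.ndim}")
        if self.data.ndim == 2:
            raise ValueError("not a 3D stack")
        if any(n < 1 for n in self.data.shape):
            raise ValueError("each axis needs at least one voxel")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.dtype_range is None:
            if np.issubdtype(self.data.dtype, np.integer):
                info = np.iinfo(self.data.dtype)
                self.dtype_range = (float(info.min), float(info.max))
            else:
                self.dtype_range = (float(self.data.min()), float(self.data.max()))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def copy_with(self, data: np.ndarray, spacing: Sequence[float] | None = None) -> "VoxelGrid":
        sp = tuple(spacing) if spacing is not None else self.spacing
        return VoxelGrid(data, sp, dtype_range=self.dtype_range)


@dataclass
class BinaryMask:
    """A 3D {0,1} field; foreground = vessel.

    Stored as ``uint8``; shares the spacing contract of :class:`VoxelGrid`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("not a 3D stack")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def copy_with(self, data: np.ndarray, spacing: Sequence[float] | None = None) -> "BinaryMask":
        sp = tuple(spacing) if spacing is not None else self.spacing
        return BinaryMask(data, sp)


@dataclass
class ROIBox:
    """Axis-aligned region of interest with half-open voxel bounds.

    ``lo`` is inclusive, ``hi`` exclusive, both in ``(z, y, x)`` index order.
    An optional mask variant restricts the ROI to an arbitrary voxel set.
    """

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        self.lo = tuple(int(v) for v in self.lo)  # type: ignore[assignment]
        self.hi = tuple(int(v) for v in self.hi)  # type: ignore[assignment]
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("lo and hi must each have three entries (z, y, x)")
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"ROI requires lo < hi per axis, got lo={self.lo} hi={self.hi}")
        if any(l < 0 for l in self.lo):
            raise ValueError("ROI bounds must be non-negative")

    @classmethod
    def full(cls, shape: Sequence[int]) -> "ROIBox":
        return cls((0, 0, 0), tuple(int(n) for n in shape))

    def check_within(self, shape: Sequence[int]) -> None:
        if any(h > n for h, n in zip(self.hi, shape)):
            raise ValueError(f"ROI {self.lo}:{self.hi} exceeds grid shape {tuple(shape)}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(np.prod([h - l for l, h in zip(self.lo, self.hi)]))


@dataclass
class LandmarkSet:
    """An ordered set of named anatomical points in physical µm.

    The canonical use is 11 landmarks spread along the anterior–posterior,
    left–right and dorso-ventral body axes, but any ≥3 non-collinear named
    points support a rigid fit.
    """

    names: list[str]
    points: np.ndarray  # (N, 3) physical (x, y, z) µm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array of (x, y, z) µm")
        if len(self.names) != len(self.points):
            raise ValueError("one name per point required")

    def __len__(self) -> int:
        return len(self.names)

    def is_collinear(self, tol: float = 1e-9) -> bool:
        if len(self) < 3:
            return True
        centered = self.points - self.points.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        return bool(s[1] <= tol * max(s[0], 1.0))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, spacing: Sequence[float]) -> VoxelGrid:
    """Read a multi-page TIFF stack as a :class:`VoxelGrid`.

    Spacing carries no silent default — the caller must state the physical
    voxel size ``(sz, sy, sx)`` in µm (from acquisition metadata or config).
    """
    if spacing is None:
        raise ValueError("missing spacing: physical voxel size (sz, sy, sx) in µm is required")
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile error text varies
        raise ValueError(f"unreadable TIFF file {path}: {exc}") from exc
    if data.ndim == 2:
        raise ValueError(f"{path}: not a 3D stack (single page)")
    if data.ndim != 3:
        raise ValueError(f"{path}: not a 3D stack (ndim={data.ndim})")
    return VoxelGrid(data, tuple(spacing))


def write_volume(path: str | Path, grid: VoxelGrid) -> None:
    """Write a grid as multi-page TIFF; round-trips bit-exactly for 8/16-bit."""
    # explicit photometric: stacks with 3- or 4-long axes must not be
    # misinterpreted as RGB planes
    tifffile.imwrite(Path(path), grid.data, photometric="minisblack")


def read_mask(path: str | Path, spacing: Sequence[float], inverted: bool = False) -> BinaryMask:
    """Read a binary mask TIFF; ``inverted`` reads 0=vessel, 255=background."""
    grid = read_volume(path, spacing)
    if inverted:
        data = (grid.data == 0).astype(np.uint8)
    else:
        data = (grid.data > 0).astype(np.uint8)
    return BinaryMask(data, tuple(spacing))


def write_mask(path: str | Path, mask: BinaryMask, inverted: bool = False) -> None:
    if inverted:
        out = np.where(mask.data > 0, 0, 255).astype(np.uint8)
    else:
        out = (mask.data * 255).astype(np.uint8)
    tifffile.imwrite(Path(path), out)


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read landmarks from CSV with header ``name,x_um,y_um,z_um``."""
    df = pd.read_csv(path)
    required = ["name", "x_um", "y_um", "z_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns: {missing}")
    return LandmarkSet(
        names=[str(n) for n in df["name"]],
        points=df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
    )


def write_landmarks(path: str | Path, lm: LandmarkSet) -> None:
    pd.DataFrame(
        {"name": lm.names, "x_um": lm.points[:, 0], "y_um": lm.points[:, 1], "z_um": lm.points[:, 2]}
    ).to_csv(path, index=False)


def read_roi(path: str | Path) -> ROIBox:
    """Read an ROI as JSON ``{"lo": [z,y,x], "hi": [z,y,x]}``."""
    with open(path) as fh:
        obj = json.load(fh)
    return ROIBox(tuple(obj["lo"]), tuple(obj["hi"]))


def write_roi(path: str | Path, roi: ROIBox) -> None:
    with open(path, "w") as fh:
        json.dump({"lo": list(roi.lo), "hi": list(roi.hi)}, fh)


def read_transform_matrix(path: str | Path) -> np.ndarray:
    """Read a rigid transform stored as a row-major 4×4 homogeneous matrix (µm)."""
    with open(path) as fh:
        obj = json.load(fh)
    mat = np.asarray(obj["matrix"], dtype=float)
    if mat.shape != (4, 4):
        raise ValueError(f"expected 4x4 matrix, got {mat.shape}")
    return mat


def write_transform_matrix(path: str | Path, matrix: np.ndarray, meta: dict | None = None) -> None:
    obj = {"matrix": np.asarray(matrix, dtype=float).tolist()}
    if meta:
        obj.update(meta)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)


# ---------------------------------------------------------------------------
# Geometry operations
# ---------------------------------------------------------------------------

def downsample_xy(grid: VoxelGrid, target_xy: int):
    """Resample the lateral (x, y) axes to ``target_xy`` pixels by bilinear
    interpolation, leaving z untouched.

    Mirrors the pipeline's 1920→512 lateral downsampling used to keep the
    distance-map and skeleton stages tractable.  Output spacing satisfies
    ``sx_out = sx_in * (nx_in / nx_out)`` (same for y).  Accepts a
    :class:`VoxelGrid` or a :class:`BinaryMask` (the latter is interpolated
    and re-binarised at 0.5).
    """
    if target_xy <= 0:
        raise ValueError("target_xy must be positive")
    nz, ny, nx = grid.data.shape
    if target_xy > nx or target_xy > ny:
        raise ValueError(f"target {target_xy} exceeds lateral size ({ny}, {nx})")
    is_mask = isinstance(grid, BinaryMask)
    src = grid.data.astype(np.float64)
    out = resize(
        src,
        (nz, target_xy, target_xy),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    sz, sy, sx = grid.spacing
    new_spacing = (sz, sy * (ny / target_xy), sx * (nx / target_xy))
    if is_mask:
        return BinaryMask((out >= 0.5).astype(np.uint8), new_spacing)
    return grid.copy_with(out, new_spacing)


def crop_to_roi(grid, roi: ROIBox):
    """Crop a grid or mask to the ROI box; returned shape = hi − lo per axis."""
    roi.check_within(grid.data.shape)
    sub = grid.data[roi.slices].copy()
    return grid.copy_with(sub)


_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


def max_intensity_projection(grid, axis: str = "z") -> np.ndarray:
    """Maximum intensity projection along ``axis`` ('z', 'y' or 'x')."""
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of z|y|x, got {axis!r}")
    return grid.data.max(axis=_AXIS_INDEX[axis])
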