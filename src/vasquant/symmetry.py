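"""Intra-sample left–right symmetry of a segmented vasculature.

The midline is a straight line fitted to user-supplied anatomical axis
points (e.g. basal aorta and the bifurcation anchors).  The mask is rotated
in-plane so the anterior–posterior axis runs along image y, split at the
midline x-column, the right half mirrored onto the left, and the two
hemispheres compared by voxel overlap plus per-hemisphere volume and
skeleton length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import BinaryMask, LandmarkSet
from .quantify import network_length, skeletonize_3d
from .registration import RigidTransform, apply_rigid
from .similarity import dice_coefficient

__all__ = [
    "MidlineAxis",
    "SymmetryReport",
    "align_ap_axis",
    "mirror_right_to_left",
    "left_right_report",
]


@dataclass
class MidlineAxis:
    """≥2 points (physical µm, x-y-z) along the anterior–posterior midline."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("axis points must be (N, 3) in µm")
        if len(self.points) < 2:
            raise ValueError("need at least two axis points")
        if np.allclose(self.points.max(axis=0), self.points.min(axis=0)):
            raise ValueError("axis points are coincident")

    @classmethod
    def from_landmarks(cls, lm: LandmarkSet) -> "MidlineAxis":
        return cls(lm.points)

    def direction_xy(self) -> np.ndarray:
        """Unit direction of the fitted line, projected to the xy-plane."""
        xy = self.points[:, :2]
        centered = xy - xy.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        d = vt[0]
        if np.linalg.norm(d) < 1e-12:
            raise ValueError("axis direction degenerate in the xy-plane")
        if d[1] < 0:  # orient toward +y
            d = -d
        return d / np.linalg.norm(d)


@dataclass
class SymmetryReport:
    volume_left_um3: float
    volume_right_um3: float
    length_left_voxels: int
    length_right_voxels: int
    dice_lr: float
    overlap_mask: BinaryMask
    midline_x: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "volume_left_um3": self.volume_left_um3,
            "volume_right_um3": self.volume_right_um3,
            "length_left_voxels": self.length_left_voxels,
            "length_right_voxels": self.length_right_voxels,
            "dice_lr": self.dice_lr,
            "midline_x": self.midline_x,
            "flags": list(self.flags),
        }


def align_ap_axis(
    mask: BinaryMask, axis: MidlineAxis
) -> tuple[BinaryMask, RigidTransform, MidlineAxis]:
    """Rotate about z so the fitted axis direction is parallel to image y.

    Returns the rotated mask, the transform used, and the axis points mapped
    through it.
    """
    d = axis.direction_xy()
    # the axis sits at angle α from +y toward +x; the CCW rotation Rz(α)
    # maps it back onto +y (x' = sin(α − θ) vanishes at θ = α)
    angle = np.arctan2(d[0], d[1])  # radians, x-component over y-component
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    nz, ny, nx = mask.shape
    sz, sy, sx = mask.spacing
    center = np.array([(nx - 1) / 2 * sx, (ny - 1) / 2 * sy, (nz - 1) / 2 * sz])
    xf = RigidTransform(R, np.zeros(3), center)
    rotated = apply_rigid(mask, xf, interpolation="nearest")
    new_points = xf.apply_points(axis.points)
    return rotated, xf, MidlineAxis(new_points)


def _midline_column(axis: MidlineAxis, spacing_x: float) -> float:
    """Midline x in voxels: mean x of the axis points, rounded to the nearest
    half-integer (a half-integer midline is the plane between two columns)."""
    mean_x_vox = float(axis.points[:, 0].mean()) / spacing_x
    return float(np.round(mean_x_vox * 2.0) / 2.0)


def mirror_right_to_left(
    mask: BinaryMask, midline_x: float
) -> tuple[BinaryMask, BinaryMask, list[str]]:
    """Split a mask at the midline and reflect the right half onto the left
    half's frame.

    ``midline_x`` may be an integer voxel column (which belongs to neither
    hemisphere) or a half-integer plane between two columns.  Reflection
    maps column x to 2·midline − x (voxel-centre convention), a bijection on
    the lattice, so foreground counts are preserved exactly and reflecting
    twice returns the right half unchanged.  Returns full-shape masks
    (left hemisphere, mirrored right hemisphere) plus flags.
    """
    nz, ny, nx = mask.shape
    if not (0 <= midline_x < nx):
        raise ValueError(f"midline {midline_x} outside x-range [0, {nx})")
    if (2 * midline_x) != int(2 * midline_x):
        raise ValueError("midline must be an integer or half-integer column")
    flags: list[str] = []
    if midline_x < 1 or midline_x > nx - 2:
        flags.append("midline-at-edge")

    data = mask.data
    xs_all = np.arange(nx)
    left_cols = xs_all[xs_all < midline_x]
    right_cols = xs_all[xs_all > midline_x]
    left = np.zeros_like(data)
    left[:, :, left_cols] = data[:, :, left_cols]
    right = np.zeros_like(data)
    right[:, :, right_cols] = data[:, :, right_cols]

    mirrored = np.zeros_like(data)
    refl = np.rint(2 * midline_x - right_cols).astype(int)
    keep = refl >= 0
    mirrored[:, :, refl[keep]] = right[:, :, right_cols[keep]]
    return mask.copy_with(left), mask.copy_with(mirrored), flags


def left_right_report(
    mask: BinaryMask,
    axis: MidlineAxis,
    midline_x: float | None = None,
    align: bool = True,
) -> SymmetryReport:
    """Full symmetry analysis: align, split, mirror, compare.

    Per-hemisphere volume and skeleton network length use the same operators
    as the main quantification stack so left/right values are directly
    comparable; ``dice_lr`` is the Dice overlap of the left hemisphere with
    the mirrored right; the overlap mask marks voxels that are vessel on
    both sides (the voxel-wise majority agreement of the two hemispheres).
    """
    flags: list[str] = []
    work, ax = mask, axis
    if align:
        work, _, ax = align_ap_axis(mask, axis)
    if midline_x is None:
        midline_x = _midline_column(ax, work.spacing[2])
        midline_x = float(np.clip(midline_x, 0, work.shape[2] - 1))

    left, mirrored_right, mflags = mirror_right_to_left(work, midline_x)
    flags.extend(mflags)
    if work.foreground_count == 0:
        flags.append("empty-mask")

    vol = work.voxel_volume_um3
    volume_left = left.foreground_count * vol
    xs_all = np.arange(work.shape[2])
    right_count = int(work.data[:, :, xs_all > midline_x].sum())
    volume_right = right_count * vol

    def hemi_length(hemi: BinaryMask) -> int:
        if hemi.foreground_count == 0:
            return 0
        return network_length(skeletonize_3d(hemi))[0]

    length_left = hemi_length(left)
    length_right = hemi_length(mirrored_right)
    dice_lr = dice_coefficient(left, mirrored_right)
    overlap = work.copy_with(left.data & mirrored_right.data)
    return SymmetryReport(
        volume_left_um3=volume_left,
        volume_right_um3=volume_right,
        length_left_voxels=length_left,
        length_right_voxels=length_right,
        dice_lr=dice_lr,
        overlap_mask=overlap,
        midline_x=midline_x,
        flags=flags,
    )
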