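"""Rigid inter-sample registration and population average maps.

Two routes into a common coordinate system are provided, mirroring typical
practice for light-sheet embryo data: a manual route fitting a rigid
transform to named anatomical landmarks (least squares, no scaling), and an
automatic route that searches orientations exhaustively on a coarse image
pyramid, keeps the best few candidates, and refines them by derivative-free
optimisation.  Registered binary masks are averaged voxel-wise into a
population average map (PAM) whose values are per-voxel overlap fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation
from skimage.registration import phase_cross_correlation

from .core_io import BinaryMask, LandmarkSet, VoxelGrid

__all__ = [
    "RigidTransform",
    "AutoRegParams",
    "RegistrationResult",
    "PopulationAverageMap",
    "fit_landmark_rigid",
    "register_automatic_rigid",
    "apply_rigid",
    "build_population_average_map",
]

# Axis-order flip between physical (x, y, z) vectors and (z, y, x) arrays.
_J = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


@dataclass
class RigidTransform:
    """Rotation + translation acting on physical (x, y, z) coordinates in µm.

    Maps a point p to ``R @ (p - center) + center + t``.
    """

    R: np.ndarray
    t: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-9):
            raise ValueError("R must be orthogonal (R^T R = I within 1e-9)")
        if not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-9):
            raise ValueError("R must be a proper rotation (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), np.zeros(3))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (self.R @ (pts - self.center).T).T + self.center + self.t

    def inverse(self) -> "RigidTransform":
        Rinv = self.R.T
        # q = R(p-c)+c+t  =>  p = R^T(q-c-t)+c
        return RigidTransform(Rinv, -Rinv @ self.t, self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        m = self.as_matrix() @ other.as_matrix()
        R = m[:3, :3]
        # re-express with this transform's center
        c = self.center
        t = m[:3, 3] - c + R @ c
        return RigidTransform(R, t, c)

    def as_matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix (row-major, physical µm, x-y-z order)."""
        m = np.eye(4)
        m[:3, :3] = self.R
        m[:3, 3] = self.center + self.t - self.R @ self.center
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray, center: np.ndarray | None = None) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        R = m[:3, :3]
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        t = m[:3, 3] - c + R @ c
        return cls(R, t, c)


@dataclass
class AutoRegParams:
    """Settings of the automatic rigid search.

    The orientation space is scanned on a coarse Euler-angle grid at the
    coarsest pyramid level; the ``n_orientations_kept`` best candidates (by
    the squared-difference objective, translation solved exactly per
    orientation via FFT cross-correlation) are refined through the remaining
    levels by Nelder–Mead on the Euler angles.
    """

    n_orientations_kept: int = 5
    downsample_factors: tuple[int, ...] = (6, 4, 2)
    angular_grid_step: float = 30.0
    refine_step: float = 5.0
    max_shift_um: float | None = None
    low_confidence_dice: float = 0.2

    def __post_init__(self) -> None:
        self.downsample_factors = tuple(int(f) for f in self.downsample_factors)  # type: ignore[assignment]
        if list(self.downsample_factors) != sorted(self.downsample_factors, reverse=True):
            raise ValueError("downsample_factors must be descending")
        if self.n_orientations_kept < 1:
            raise ValueError("n_orientations_kept must be >= 1")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    objective: float
    low_confidence: bool = False


@dataclass
class PopulationAverageMap:
    """Voxel-wise mean of co-registered binary masks; values are overlap
    fractions in [0, 1] and ``mean_map * n_samples`` is an integer count."""

    mean_map: np.ndarray
    n_samples: int
    template_id: str
    spacing: tuple[float, float, float]


# ---------------------------------------------------------------------------
# Landmark-based fit
# ---------------------------------------------------------------------------

def fit_landmark_rigid(
    moving: LandmarkSet, target: LandmarkSet
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit (Kabsch, no scaling) mapping moving landmarks
    onto target landmarks.

    Returns the transform (centre = moving centroid) and the RMS residual in
    µm.  Requires ≥3 non-collinear points with matching names in order.
    """
    if len(moving) < 3 or len(target) < 3:
        raise ValueError("rigid fit needs at least 3 landmarks")
    if moving.names != target.names:
        raise ValueError("landmark names/order must match between sets")
    if moving.is_collinear() or target.is_collinear():
        raise ValueError("landmarks are collinear; rotation is not identifiable")

    P = moving.points
    Q = target.points
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # with center = cp:  q = R(p - cp) + cp + t  =>  t = cq - cp
    t = cq - cp
    xf = RigidTransform(R, t, cp)
    resid = xf.apply_points(P) - Q
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return xf, rms


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _index_affine(xf: RigidTransform, spacing: tuple[float, float, float]):
    """Matrix/offset mapping output (z,y,x) indices to input indices for
    scipy.ndimage.affine_transform (which pulls values from the input)."""
    S = np.diag(spacing)  # (z, y, x) physical scale
    R_zyx = _J @ xf.R @ _J
    c_zyx = _J @ xf.center
    t_zyx = _J @ xf.t
    Rinv = R_zyx.T
    Sinv = np.diag(1.0 / np.asarray(spacing))
    M = Sinv @ Rinv @ S
    off = Sinv @ (Rinv @ (-c_zyx - t_zyx) + c_zyx)
    return M, off


def apply_rigid(grid, xf: RigidTransform, interpolation: str = "linear"):
    """Resample a grid or mask through a rigid transform.

    The output stays on the input lattice; masks must use nearest-neighbour
    interpolation and remain {0,1}.  ``apply_rigid(g, identity)`` is the
    identity.
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation mode {interpolation!r}")
    is_mask = isinstance(grid, BinaryMask)
    if is_mask and interpolation == "linear":
        interpolation = "nearest"
    order = 0 if interpolation == "nearest" else 1
    M, off = _index_affine(xf, grid.spacing)
    out = ndimage.affine_transform(
        grid.data.astype(np.float64), M, offset=off, order=order, mode="constant", cval=0.0
    )
    if is_mask:
        return grid.copy_with((out > 0.5).astype(np.uint8))
    return grid.copy_with(out)


# ---------------------------------------------------------------------------
# Automatic rigid registration
# ---------------------------------------------------------------------------

def _as_float_volume(img) -> tuple[np.ndarray, tuple[float, float, float]]:
    if isinstance(img, (BinaryMask, VoxelGrid)):
        return img.data.astype(np.float64), img.spacing
    raise TypeError("expected VoxelGrid or BinaryMask")


def _downsample(vol: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return vol
    return ndimage.zoom(vol, 1.0 / factor, order=1)


def _rotate_about_center(vol: np.ndarray, R: np.ndarray, spacing_zyx: np.ndarray) -> np.ndarray:
    """Rotate a volume about its physical centre (pull resampling, linear)."""
    S = np.diag(spacing_zyx)
    Sinv = np.diag(1.0 / spacing_zyx)
    R_zyx = _J @ R @ _J
    center_idx = (np.asarray(vol.shape) - 1) / 2.0
    c_phys = S @ center_idx
    M = Sinv @ R_zyx.T @ S
    off = Sinv @ (R_zyx.T @ (-c_phys) + c_phys)
    return ndimage.affine_transform(vol, M, offset=off, order=1, mode="constant", cval=0.0)


def _best_shift_ssd(
    target: np.ndarray,
    moving: np.ndarray,
    max_shift_vox: np.ndarray | None,
    target_fft: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Best integer (z,y,x) shift of `moving` minimising SSD against `target`
    by circular FFT cross-correlation; returns (shift, ssd)."""
    F = np.fft.fftn(target) if target_fft is None else target_fft
    G = np.fft.fftn(moving)
    corr = np.fft.ifftn(F * np.conj(G)).real
    if max_shift_vox is not None:
        grids = np.meshgrid(
            *[np.minimum(np.arange(n), n - np.arange(n)) for n in corr.shape], indexing="ij"
        )
        allow = np.ones(corr.shape, dtype=bool)
        for g, m in zip(grids, max_shift_vox):
            allow &= g <= m
        corr = np.where(allow, corr, -np.inf)
    idx = np.unravel_index(int(np.argmax(corr)), corr.shape)
    shift = np.array(
        [i if i <= n // 2 else i - n for i, n in zip(idx, corr.shape)], dtype=float
    )
    cmax = float(corr[idx])
    ssd = float((target**2).sum() + (moving**2).sum() - 2.0 * cmax)
    # normalised correlation: invariant to the interpolation mass an
    # off-lattice rotation sheds, unlike raw SSD
    denom = float(np.sqrt((target**2).sum() * (moving**2).sum()))
    ncc = cmax / denom if denom > 0 else 0.0
    return shift, ssd, ncc


def _euler_grid(step: float) -> np.ndarray:
    """Full-orientation intrinsic z-y-x Euler grid with the given step (deg)."""
    a = np.arange(-180.0, 180.0, step)
    b = np.arange(-90.0, 90.0 + 1e-9, step)
    c = np.arange(-180.0, 180.0, step)
    grid = np.array(np.meshgrid(a, b, c, indexing="ij")).reshape(3, -1).T
    return grid


def register_automatic_rigid(
    moving, target, params: AutoRegParams | None = None
) -> RegistrationResult:
    """Automatic rigid registration by exhaustive coarse orientation search
    plus multi-resolution refinement.

    At the coarsest pyramid level every orientation on the Euler grid is
    scored by the squared-difference objective with the translation solved
    exactly per orientation (FFT cross-correlation).  The best
    ``n_orientations_kept`` candidates are refined with Nelder–Mead through
    the finer levels; the final sub-voxel translation comes from upsampled
    phase correlation at full resolution.  A result whose post-registration
    overlap is negligible is flagged low-confidence rather than returned
    silently.
    """
    params = params or AutoRegParams()
    mov, spacing = _as_float_volume(moving)
    tgt, spacing_t = _as_float_volume(target)
    if mov.sum() == 0 or tgt.sum() == 0:
        raise ValueError("empty moving or target image")
    spacing_zyx = np.asarray(spacing, dtype=float)

    levels = {}
    level_fft = {}
    for f in params.downsample_factors:
        levels[f] = (_downsample(tgt, f), _downsample(mov, f))
        level_fft[f] = np.fft.fftn(levels[f][0])

    def objective(angles_deg: np.ndarray, level: int) -> tuple[float, np.ndarray, float]:
        """Score an orientation: −NCC at the best translation (lower=better)."""
        R = Rotation.from_euler("zyx", angles_deg, degrees=True).as_matrix()
        tg, mv = levels[level]
        rot = _rotate_about_center(mv, R, spacing_zyx * level)
        max_vox = None
        if params.max_shift_um is not None:
            max_vox = params.max_shift_um / (spacing_zyx[::-1].min() * level) * np.ones(3)
        shift, ssd, ncc = _best_shift_ssd(tg, rot, max_vox, target_fft=level_fft[level])
        return -ncc, shift, ssd

    coarse = params.downsample_factors[0]
    grid = _euler_grid(params.angular_grid_step)
    scored = []
    for ang in grid:
        score, _, _ = objective(ang, coarse)
        scored.append((score, ang))
    scored.sort(key=lambda s: s[0])
    candidates = [ang for _, ang in scored[: params.n_orientations_kept]]

    finer = params.downsample_factors[1:]
    for i, level in enumerate(finer):
        refined = []
        step = params.refine_step / (2.0**i)
        for ang in candidates:
            simplex = np.vstack([ang, ang + np.eye(3) * step])
            res = optimize.minimize(
                lambda a: objective(a, level)[0],
                ang,
                method="Nelder-Mead",
                options={
                    "initial_simplex": simplex,
                    "xatol": params.refine_step / (10.0 * (i + 1)),
                    "fatol": 1e-6,
                    "maxiter": 120 if i == 0 else 60,
                },
            )
            refined.append((res.fun, res.x))
        refined.sort(key=lambda s: s[0])
        # narrow the pool as levels get expensive
        keep = params.n_orientations_kept if i == 0 else 2
        candidates = [ang for _, ang in refined[:keep]]
        best_obj, best_ang = refined[0]

    if not finer:
        best_obj, best_ang = scored[0]

    # final sub-voxel translation at full resolution
    R = Rotation.from_euler("zyx", best_ang, degrees=True).as_matrix()
    rot_full = _rotate_about_center(mov, R, spacing_zyx)
    shift_vox, _, _ = phase_cross_correlation(
        tgt, rot_full, upsample_factor=10, normalization=None
    )
    t_phys_zyx = shift_vox * spacing_zyx
    t_xyz = (_J @ t_phys_zyx.reshape(3)).reshape(3)
    center_idx = (np.asarray(tgt.shape) - 1) / 2.0
    c_xyz = _J @ (center_idx * spacing_zyx)
    xf = RigidTransform(R, t_xyz, c_xyz)

    moved = ndimage.shift(rot_full, shift_vox, order=1, mode="constant", cval=0.0)
    inter = float(np.minimum(moved > 0.5, tgt > 0.5).sum())
    denom = float((moved > 0.5).sum() + (tgt > 0.5).sum())
    dice = 2.0 * inter / denom if denom else 0.0
    ssd_final = float(((moved - tgt) ** 2).sum())
    return RegistrationResult(xf, ssd_final, low_confidence=dice < params.low_confidence_dice)


# ---------------------------------------------------------------------------
# Population average map
# ---------------------------------------------------------------------------

def build_population_average_map(
    masks: list[BinaryMask], template_id: str = ""
) -> PopulationAverageMap:
    """Voxel-wise mean of registered binary masks.

    ``mean_map * n`` is the integer per-voxel overlap count; the mean over
    all voxels equals the mean foreground fraction of the inputs.
    """
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {shape}")
    acc = np.zeros(shape, dtype=np.float64)
    for m in masks:
        acc += m.data
    acc /= len(masks)
    return PopulationAverageMap(acc, len(masks), template_id, masks[0].spacing)
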