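"""Synthetic 3D vascular phantoms with exact ground truth.

Phantoms are unions of tubular segments rasterised on the voxel lattice by
voxel-centre-in-tube inclusion, so every truth quantity (mask volume,
centreline, per-segment radius, branch-point count, symmetry plane) is known
by construction.  The intensity renderer emulates the optics of light-sheet
fluorescence imaging of vascular reporters: solid (unlumenised) or
wall-bright (lumenised, double-peak cross-section) tube profiles, Gaussian
PSF blur, Poisson shot noise, additive Gaussian read noise and a constant
background.  Geometry is expressed in voxel units on the (z, y, x) lattice;
the default grid, 128×256×256 voxels at (0.5, 0.33, 0.33) µm, puts tube
radii of 2–12 voxels in the regime of 5–20 µm diameter cerebral vessels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, VoxelGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "Segment",
    "generate_tube_phantom",
    "generate_tree_phantom",
    "generate_symmetric_phantom",
    "render_noisy",
]

DEFAULT_SHAPE = (128, 256, 256)
DEFAULT_SPACING = (0.5, 0.33, 0.33)


@dataclass
class Segment:
    """A straight tube segment: endpoints in (z, y, x) voxel coords + radius.

    ``caps`` controls whether the rasterised tube gains hemispherical end
    caps (needed for gap-free joints inside trees); a free-standing straight
    tube is capless so its voxel count tracks the analytic cylinder volume.
    """

    p0: np.ndarray
    p1: np.ndarray
    radius: float
    caps: bool = True

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))


@dataclass
class PhantomSpec:
    """Parameters of phantom geometry and rendering.

    Geometry: grid ``shape`` (z, y, x), physical ``spacing`` µm, tube
    ``radius`` / per-depth ``radius_decay``, tree growth controls
    (``n_bifurcations``, ``branch_angle_deg`` range, ``segment_length``
    range).  Rendering: ``lumenised`` selects a bright-wall/dim-lumen
    profile of ``wall_thickness`` voxels; ``vessel_peak`` and ``background``
    are mean photon counts; ``psf_sigma`` (voxels) models the optical blur;
    ``poisson_scale`` scales shot noise (0 disables) and ``read_noise_sigma``
    is the additive Gaussian term.  ``seed`` drives all randomised geometry.
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    radius: float = 12.0
    radius_decay: float = 0.85
    n_bifurcations: int = 5
    branch_angle_deg: tuple[float, float] = (30.0, 50.0)
    segment_length: tuple[float, float] = (40.0, 60.0)
    z_jitter: float = 0.15
    lumenised: bool = False
    wall_thickness: float = 2.0
    vessel_peak: float = 150.0
    lumen_level: float = 45.0
    background: float = 10.0
    psf_sigma: float = 1.0
    poisson_scale: float = 1.0
    read_noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if any(n <= 0 for n in self.shape):
            raise ValueError("shape must be positive")
        if min(self.vessel_peak, self.background, self.lumen_level) < 0:
            raise ValueError("intensity parameters must be non-negative")


@dataclass
class PhantomTruth:
    """Analytically known ground truth of a generated phantom."""

    mask: BinaryMask
    centerline_voxels: np.ndarray  # (N, 3) integer (z, y, x)
    segments: list[Segment]
    branch_points: np.ndarray  # (K, 3) float (z, y, x)
    branch_count: int
    centerline_length_voxels: float
    true_volume_um3: float
    symmetry_plane_x: int | None = None
    injected_voxels: int = 0
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------

def _paint_segment(mask: np.ndarray, seg: Segment) -> None:
    """Set voxels whose centre lies within `radius` of the segment."""
    lo = np.floor(np.minimum(seg.p0, seg.p1) - seg.radius - 1).astype(int)
    hi = np.ceil(np.maximum(seg.p0, seg.p1) + seg.radius + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, mask.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = seg.p1 - seg.p0
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.linalg.norm(pts - seg.p0, axis=-1)
    else:
        t_raw = ((pts - seg.p0) @ d) / L2
        t = np.clip(t_raw, 0.0, 1.0)
        proj = seg.p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
        if not seg.caps:
            dist = np.where((t_raw < 0.0) | (t_raw > 1.0), np.inf, dist)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= dist <= seg.radius


def _rasterise(segments: list[Segment], shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for seg in segments:
        _paint_segment(mask, seg)
    return mask


def _centerline_voxels(segments: list[Segment]) -> np.ndarray:
    pts = []
    for seg in segments:
        n = max(int(np.ceil(seg.length * 3)), 2)
        t = np.linspace(0.0, 1.0, n)
        pts.append(seg.p0 + t[:, None] * (seg.p1 - seg.p0))
    all_pts = np.rint(np.concatenate(pts)).astype(int)
    return np.unique(all_pts, axis=0)


def _segment_in_bounds(seg: Segment, shape, margin: float) -> bool:
    lo = np.minimum(seg.p0, seg.p1) - seg.radius - margin
    hi = np.maximum(seg.p0, seg.p1) + seg.radius + margin
    return bool(np.all(lo >= 0) and np.all(hi < np.asarray(shape)))


def _sample_points(seg: Segment, step: float = 0.75) -> np.ndarray:
    n = max(int(np.ceil(seg.length / step)), 2)
    t = np.linspace(0.0, 1.0, n)
    return seg.p0 + t[:, None] * (seg.p1 - seg.p0)


def _min_clearance_ok(
    cand: Segment, existing: list[Segment], share_endpoint_with: set[int], pad: float = 2.0
) -> bool:
    """Candidate must stay clear of every non-adjacent existing segment."""
    cpts = _sample_points(cand)
    for i, seg in enumerate(existing):
        if i in share_endpoint_with:
            continue
        spts = _sample_points(seg)
        dmin = np.sqrt(
            ((cpts[:, None, :] - spts[None, :, :]) ** 2).sum(axis=-1)
        ).min()
        if dmin < cand.radius + seg.radius + pad:
            return False
    return True


def _truth_from_segments(
    segments: list[Segment],
    branch_points: list[np.ndarray],
    shape,
    spacing,
    flags: list[str] | None = None,
) -> tuple[BinaryMask, PhantomTruth]:
    data = _rasterise(segments, tuple(shape))
    mask = BinaryMask(data.astype(np.uint8), tuple(spacing))
    truth = PhantomTruth(
        mask=mask,
        centerline_voxels=_centerline_voxels(segments),
        segments=list(segments),
        branch_points=np.asarray(branch_points, dtype=float).reshape(-1, 3),
        branch_count=len(branch_points),
        centerline_length_voxels=float(sum(s.length for s in segments)),
        true_volume_um3=float(data.sum()) * mask.voxel_volume_um3,
        flags=list(flags or []),
    )
    return mask, truth


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_tube_phantom(
    spec: PhantomSpec, control_points: np.ndarray | None = None
) -> tuple[BinaryMask, PhantomTruth]:
    """A single straight or polyline tube with exact truth.

    ``control_points`` is an (N≥2, 3) array of (z, y, x) voxel coordinates;
    by default the tube runs along y through the volume centre.  A radius
    below half a voxel yields a single-voxel-wide line, flagged degenerate.
    """
    shape = spec.shape
    if control_points is None:
        # integer centre: a perfectly symmetric even-width tube is a thinning
        # pathology (the medial axis falls between voxels)
        cz, _, cx = [(n - 1) // 2 for n in shape]
        margin = float(np.ceil(spec.radius)) + 2
        control_points = np.array(
            [[cz, margin, cx], [cz, shape[1] - 1 - margin, cx]]
        )
    control_points = np.asarray(control_points, dtype=float)
    straight = len(control_points) == 2
    segments = [
        Segment(control_points[i], control_points[i + 1], spec.radius, caps=not straight)
        for i in range(len(control_points) - 1)
    ]
    for seg in segments:
        if not _segment_in_bounds(seg, shape, margin=0.0):
            raise ValueError("tube exceeds volume bounds")
    flags = []
    if spec.radius < 0.5:
        flags.append("degenerate-radius")
    return _truth_from_segments(segments, [], shape, spec.spacing, flags)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _branch_directions(
    parent: np.ndarray, angle_deg: float, rng: np.random.Generator, z_jitter: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two child directions splayed ±angle from the parent, mostly in-plane."""
    a = np.deg2rad(angle_deg)
    # in-plane (y, x) rotation of the parent's lateral direction
    py, px = parent[1], parent[2]
    base = np.arctan2(px, py)
    d1 = np.array([rng.uniform(-z_jitter, z_jitter), np.cos(base + a), np.sin(base + a)])
    d2 = np.array([rng.uniform(-z_jitter, z_jitter), np.cos(base - a), np.sin(base - a)])
    return _unit(d1), _unit(d2)


def generate_tree_phantom(
    spec: PhantomSpec, seed: int | None = None, max_retries: int = 40
) -> tuple[BinaryMask, PhantomTruth]:
    """A random bifurcating tree of tube segments with exact truth.

    The tree grows from a root segment by repeatedly bifurcating a randomly
    chosen tip until exactly ``spec.n_bifurcations`` internal branch points
    exist.  New segments must stay inside the volume and keep a clearance of
    two voxels plus radii from every non-adjacent segment (so thinning can
    recover the topology exactly); a geometry that cannot be placed is
    re-drawn up to ``max_retries`` times before erroring.
    """
    if spec.n_bifurcations < 0:
        raise ValueError("n_bifurcations must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = np.asarray(spec.shape)

    for _ in range(max_retries):
        root_start = np.array(
            [float(shape[0] // 2), spec.radius + 4.0, float(shape[2] // 2)]
        )
        root_dir = np.array([0.0, 1.0, 0.0])
        root_len = rng.uniform(*spec.segment_length)
        root = Segment(root_start, root_start + root_dir * root_len, spec.radius)
        if not _segment_in_bounds(root, shape, 1.0):
            continue
        segments = [root]
        # tips: (segment index, direction, depth)
        tips = [(0, root_dir, 0)]
        branch_pts: list[np.ndarray] = []
        ok = True
        for _ in range(spec.n_bifurcations):
            placed = False
            for _attempt in range(60):
                ti = int(rng.integers(len(tips)))
                si, pdir, depth = tips[ti]
                parent = segments[si]
                angle = rng.uniform(*spec.branch_angle_deg)
                d1, d2 = _branch_directions(pdir, angle, rng, spec.z_jitter)
                r_child = max(parent.radius * spec.radius_decay, 1.5)
                children = []
                good = True
                for d in (d1, d2):
                    ln = rng.uniform(*spec.segment_length)
                    child = Segment(parent.p1, parent.p1 + d * ln, r_child)
                    if not _segment_in_bounds(child, shape, 1.0):
                        good = False
                        break
                    children.append(child)
                if good:
                    adjacent = {si} | {
                        j
                        for j, s in enumerate(segments)
                        if np.linalg.norm(s.p1 - parent.p1) < 1e-6
                        or np.linalg.norm(s.p0 - parent.p1) < 1e-6
                    }
                    for child in children:
                        if not _min_clearance_ok(child, segments, adjacent):
                            good = False
                            break
                if not good:
                    continue
                i0 = len(segments)
                segments.extend(children)
                tips.pop(ti)
                tips.append((i0, _unit(children[0].p1 - children[0].p0), depth + 1))
                tips.append((i0 + 1, _unit(children[1].p1 - children[1].p0), depth + 1))
                branch_pts.append(parent.p1.copy())
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return _truth_from_segments(segments, branch_pts, spec.shape, spec.spacing)
    raise RuntimeError(
        f"could not place a tree with {spec.n_bifurcations} bifurcations "
        f"in shape {spec.shape} after {max_retries} retries"
    )


def generate_symmetric_phantom(
    spec: PhantomSpec,
    seed: int | None = None,
    inject_right_segment: Segment | None = None,
) -> tuple[BinaryMask, PhantomTruth]:
    """A bilaterally symmetric phantom: one hemisphere tree mirrored across
    the midline plane x = nx/2 − 0.5 (between the two central columns of an
    even-width grid).

    ``inject_right_segment`` adds an extra right-side-only tube; the number
    of foreground voxels it contributes is recorded in the truth so
    asymmetry detection can be validated against an exact count.
    """
    nz, ny, nx = spec.shape
    if nx % 2 != 0:
        raise ValueError("symmetric phantom needs an even x-extent")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    # grow the hemisphere tree in the right half (x > nx/2)
    half_spec = PhantomSpec(
        shape=(nz, ny, nx),
        spacing=spec.spacing,
        radius=spec.radius,
        radius_decay=spec.radius_decay,
        n_bifurcations=spec.n_bifurcations,
        branch_angle_deg=spec.branch_angle_deg,
        segment_length=spec.segment_length,
        z_jitter=spec.z_jitter,
        seed=int(rng.integers(2**31 - 1)),
    )
    # root displaced into the right hemisphere, growing along +y
    for _ in range(40):
        mask_r, truth_r = generate_tree_phantom(half_spec, seed=int(rng.integers(2**31 - 1)))
        # shift tree into the right half if needed
        xs = np.array([[s.p0[2], s.p1[2]] for s in truth_r.segments])
        x_min = xs.min() - spec.radius - 1
        offset = max(0.0, nx / 2.0 + 1.0 - x_min)
        segs = [
            Segment(s.p0 + [0, 0, offset], s.p1 + [0, 0, offset], s.radius)
            for s in truth_r.segments
        ]
        if all(_segment_in_bounds(s, spec.shape, 0.0) for s in segs):
            break
    else:
        raise RuntimeError("could not fit hemisphere tree in the right half")

    right = _rasterise(segs, spec.shape)
    right[:, :, : nx // 2] = False  # hemisphere strictly right of the midline
    left = right[:, :, ::-1].copy()  # reflect across the plane between columns
    injected = 0
    if inject_right_segment is not None:
        before = int(right.sum())
        _paint_segment(right, inject_right_segment)
        right[:, :, : nx // 2] = False
        injected = int(right.sum()) - before
    data = right | left

    mask = BinaryMask(data.astype(np.uint8), spec.spacing)
    bps = truth_r.branch_points.reshape(-1, 3) + np.array([0.0, 0.0, offset])
    truth = PhantomTruth(
        mask=mask,
        centerline_voxels=_centerline_voxels(segs),
        segments=segs,
        branch_points=bps,
        branch_count=truth_r.branch_count,
        centerline_length_voxels=truth_r.centerline_length_voxels,
        true_volume_um3=float(data.sum()) * mask.voxel_volume_um3,
        symmetry_plane_x=nx // 2,
        injected_voxels=injected,
    )
    return mask, truth


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_noisy(mask: BinaryMask, spec: PhantomSpec, seed: int | None = None) -> VoxelGrid:
    """Render a truth mask as a noisy fluorescence volume.

    Unlumenised mode paints solid tubes at ``vessel_peak``; lumenised mode
    paints a bright wall shell of ``wall_thickness`` voxels with a dimmer
    lumen, giving the double-peak cross-section of membrane-reporter
    vessels.  The clean image is blurred with a Gaussian PSF, then corrupted
    by Poisson shot noise (disabled when ``poisson_scale`` is 0) and
    additive Gaussian read noise on top of a constant background.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    m = mask.astype_bool()
    img = np.full(m.shape, float(spec.background))
    if spec.lumenised:
        edm = ndimage.distance_transform_edt(m)
        wall = m & (edm <= spec.wall_thickness)
        lumen = m & ~wall
        img[wall] += spec.vessel_peak
        img[lumen] += spec.lumen_level
    else:
        img[m] += spec.vessel_peak
    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma)
    if spec.poisson_scale > 0:
        img = rng.poisson(np.maximum(img, 0.0) * spec.poisson_scale) / spec.poisson_scale
    if spec.read_noise_sigma > 0:
        img = img + rng.normal(0.0, spec.read_noise_sigma, img.shape)
    return VoxelGrid(np.maximum(img, 0.0), mask.spacing)
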