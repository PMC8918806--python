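"""The eight-parameter morphometry stack: volume, surface, density, EDM,
skeleton, length, branch points, radius, Sholl."""

import numpy as np
import pytest

import vasquant as vq
from vasquant.quantify import (
    count_branch_points,
    euclidean_distance_map,
    mean_vessel_radius,
    network_length,
    quantify_region,
    sholl_profile,
    skeletonize_3d,
    surface_voxels,
    vascular_density,
    vascular_volume,
)


def _mask(arr, spacing=(1.0, 1.0, 1.0)):
    return vq.BinaryMask(np.asarray(arr, np.uint8), spacing)


def _edm_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Direct minimisation over all background voxels."""
    bg = np.argwhere(mask == 0)
    out = np.zeros(mask.shape, float)
    for v in np.argwhere(mask == 1):
        out[tuple(v)] = np.sqrt(((bg - v) ** 2).sum(axis=1)).min()
    return out


# ---------------------------------------------------------------------------
# counting parameters
# ---------------------------------------------------------------------------

def test_volume_arithmetic():
    m = np.zeros((10, 10, 10), np.uint8)
    m.ravel()[:100] = 1
    mask = _mask(m, (0.5, 0.33, 0.33))
    assert vascular_volume(mask) == pytest.approx(100 * 0.5 * 0.33 * 0.33)
    assert vascular_volume(_mask(np.zeros((4, 4, 4)))) == 0.0
    full = _mask(np.ones((3, 3, 3)))
    roi = vq.ROIBox.full((3, 3, 3))
    assert vascular_volume(full, roi) == pytest.approx(27.0)


@pytest.mark.parametrize(
    "size,expected", [(1, 1), (3, 26), (5, 98)]
)
def test_surface_voxels_cubes(size, expected):
    m = np.zeros((size + 4, size + 4, size + 4), np.uint8)
    m[2: 2 + size, 2: 2 + size, 2: 2 + size] = 1
    count, scaled = surface_voxels(_mask(m))
    assert count == expected
    assert scaled == pytest.approx(count * 1.0)


def test_surface_counts_roi_faces_as_exposed():
    mask = _mask(np.ones((3, 3, 3)))
    count, _ = surface_voxels(mask)
    assert count == 26  # centre voxel is the only interior one


def test_density():
    m = np.zeros((10, 10, 10), np.uint8)
    m[:5] = 1
    assert vascular_density(_mask(m)) == 0.5
    m2 = np.zeros((10, 10, 10), np.uint8)
    m2.ravel()[:100] = 1
    assert vascular_density(_mask(m2)) == pytest.approx(0.1)
    assert vascular_density(_mask(np.zeros((4, 4, 4)))) == 0.0


def test_counting_parameters_translation_invariant(rng):
    blob = (rng.random((5, 5, 5)) > 0.5).astype(np.uint8)
    a = np.zeros((16, 16, 16), np.uint8)
    a[2:7, 2:7, 2:7] = blob
    b = np.zeros((16, 16, 16), np.uint8)
    b[8:13, 7:12, 4:9] = blob
    for f in (vascular_volume, vascular_density):
        assert f(_mask(a)) == f(_mask(b))
    assert surface_voxels(_mask(a))[0] == surface_voxels(_mask(b))[0]


# ---------------------------------------------------------------------------
# EDM
# ---------------------------------------------------------------------------

def test_edm_matches_bruteforce_on_random_masks(rng):
    for _ in range(20):
        shape = tuple(rng.integers(4, 13, 3))
        m = (rng.random(shape) > 0.6).astype(np.uint8)
        if m.min() == 1:
            m[0, 0, 0] = 0
        edm = euclidean_distance_map(_mask(m)).data
        assert np.allclose(edm, _edm_bruteforce(m), atol=1e-9)


def test_edm_examples():
    m = np.zeros((9, 9, 9), np.uint8)
    m[1:8, 1:8, 1:8] = 1  # 7³ cube
    edm = euclidean_distance_map(_mask(m)).data
    assert edm[0, 0, 0] == 0.0
    assert edm[1, 4, 4] == 1.0  # face-adjacent to background
    assert edm[4, 4, 4] == 4.0  # centre of the cube
    with pytest.raises(ValueError):
        euclidean_distance_map(_mask(np.ones((3, 3, 3))))


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

def test_skeleton_single_voxel_preserved():
    m = np.zeros((5, 5, 5), np.uint8)
    m[2, 2, 2] = 1
    out = skeletonize_3d(_mask(m))
    assert np.array_equal(out.data, m)


def test_skeleton_tube_is_simple_path(small_tree):
    spec = vq.PhantomSpec(shape=(32, 64, 32), radius=3.0)
    mask, _ = vq.generate_tube_phantom(spec)
    skel = skeletonize_3d(mask)
    from vasquant.quantify import _neighbour_counts

    nb = _neighbour_counts(skel.astype_bool())
    assert skel.foreground_count > 0
    assert (nb[skel.astype_bool()] <= 2).all()  # no junctions on a straight tube
    from scipy import ndimage

    _, n = ndimage.label(skel.data, np.ones((3, 3, 3)))
    assert n == 1


def test_skeleton_preserves_component_count(rng):
    from scipy import ndimage

    m = np.zeros((20, 20, 20), np.uint8)
    m[3:6, 3:17, 3:6] = 1
    m[12:15, 4:16, 12:15] = 1  # odd cross-sections survive thinning
    skel = skeletonize_3d(_mask(m))
    s26 = np.ones((3, 3, 3))
    _, n_before = ndimage.label(m, s26)
    _, n_after = ndimage.label(skel.data, s26)
    assert n_before == n_after == 2


# ---------------------------------------------------------------------------
# length and branch points
# ---------------------------------------------------------------------------

def test_network_length_line():
    m = np.zeros((3, 60, 3), np.uint8)
    m[1, 5:55, 1] = 1
    count, cal = network_length(_mask(m, (1.0, 0.5, 1.0)))
    assert count == 50
    assert cal == pytest.approx(49 * 0.5)
    assert network_length(_mask(np.zeros((3, 3, 3)))) == (0, 0.0)


def test_branch_points_straight_and_y():
    line = np.zeros((3, 20, 3), np.uint8)
    line[1, :, 1] = 1
    assert count_branch_points(_mask(line)) == (0, 0)

    y = np.zeros((3, 16, 16), np.uint8)
    y[1, :8, 8] = 1          # stem
    for i in range(1, 7):     # two diagonal arms from (7, 8)
        y[1, 7 + i, 8 - i] = 1
        y[1, 7 + i, 8 + i] = 1
    clustered, raw = count_branch_points(_mask(y))
    assert clustered == 1


def test_branch_points_tree_phantom(small_tree):
    mask, truth, _ = small_tree
    skel = skeletonize_3d(mask)
    edm = euclidean_distance_map(mask)
    clustered, raw = count_branch_points(skel, edm)
    assert clustered == truth.branch_count
    assert raw >= clustered


def test_length_and_bp_invariant_under_90deg_rotations(small_tree):
    """Thinning processes deletion directions in a fixed order, so exact
    voxel counts may differ by a voxel or two across lattice rotations; the
    topology (branch count) must be identical."""
    mask, _, _ = small_tree
    skel = skeletonize_3d(mask)
    l0 = network_length(skel)[0]
    bp0 = count_branch_points(skel)[0]
    rot = vq.BinaryMask(np.rot90(mask.data, axes=(1, 2)).copy(), mask.spacing)
    skel_r = skeletonize_3d(rot)
    assert abs(network_length(skel_r)[0] - l0) <= max(2, 0.01 * l0)
    assert count_branch_points(skel_r)[0] == bp0


# ---------------------------------------------------------------------------
# radius
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rho", [2.0, 3.0, 4.0, 6.0])
def test_radius_recovery_tubes(rho):
    spec = vq.PhantomSpec(shape=(40, 120, 60), radius=rho)
    mask, _ = vq.generate_tube_phantom(spec)
    edm = euclidean_distance_map(mask)
    skel = skeletonize_3d(mask)
    r = mean_vessel_radius(edm, skel)
    assert abs(r - rho) <= 0.5


def test_radius_simple_and_pooled():
    m = np.zeros((5, 5, 5), np.uint8)
    m[2, 2, 2] = 1
    edm = euclidean_distance_map(_mask(m))
    skel = _mask(m)
    assert mean_vessel_radius(edm, skel) == 1.0

    spec2 = vq.PhantomSpec(shape=(40, 120, 120), radius=2.0)
    m2, _ = vq.generate_tube_phantom(
        spec2, control_points=np.array([[19, 6, 30], [19, 113, 30]])
    )
    spec4 = vq.PhantomSpec(shape=(40, 120, 120), radius=4.0)
    m4, _ = vq.generate_tube_phantom(
        spec4, control_points=np.array([[19, 6, 80], [19, 113, 80]])
    )
    both = _mask(m2.data | m4.data)
    edm = euclidean_distance_map(both)
    r2 = mean_vessel_radius(edm, skeletonize_3d(m2))
    r4 = mean_vessel_radius(edm, skeletonize_3d(m4))
    pooled = mean_vessel_radius(edm, skeletonize_3d(both))
    assert r4 > r2
    assert abs(pooled - 3.0) <= 0.5


def test_radius_empty_skeleton_errors():
    m = np.zeros((4, 4, 4), np.uint8)
    m[1, 1, 1] = 1
    edm = euclidean_distance_map(_mask(m))
    with pytest.raises(ValueError):
        mean_vessel_radius(edm, _mask(np.zeros((4, 4, 4))))


# ---------------------------------------------------------------------------
# Sholl
# ---------------------------------------------------------------------------

def test_sholl_empty_image():
    prof = sholl_profile(np.zeros((64, 64), bool), (32, 32), max_radius=20, step=5)
    assert (prof.intersections == 0).all()
    assert list(prof.radii) == [5, 10, 15, 20]


def test_sholl_defaults_match_published_settings():
    import inspect

    sig = inspect.signature(sholl_profile)
    assert sig.parameters["max_radius"].default == 700.0
    assert sig.parameters["step"].default == 5.0


def test_sholl_single_ray():
    img = np.zeros((64, 64), bool)
    img[32, 32:60] = True  # ray to the right of the centre
    prof = sholl_profile(img, (32, 32), max_radius=25, step=5)
    assert list(prof.intersections) == [1, 1, 1, 1, 1]


def test_sholl_y_tree_angular_runs():
    """A Y bifurcating at radius 10 crosses one shell once, later shells twice."""
    img = np.zeros((80, 80), bool)
    cy, cx = 40, 40
    for r in range(0, 11):
        img[cy, cx + r] = True  # stem along +x
    for i in range(1, 12):
        img[cy - i, cx + 10 + i] = True  # upper arm
        img[cy + i, cx + 10 + i] = True  # lower arm
    prof = sholl_profile(img, (cy, cx), max_radius=15, step=5)
    assert prof.intersections[0] == 1   # r=5: stem only
    assert prof.intersections[2] == 2   # r=15: two arms


def test_sholl_center_validation():
    with pytest.raises(ValueError):
        sholl_profile(np.zeros((10, 10), bool), (20, 5))


# ---------------------------------------------------------------------------
# full record
# ---------------------------------------------------------------------------

def test_quantify_region_tree_truth(small_tree):
    mask, truth, _ = small_tree
    rec = quantify_region(mask, downsample_target=None)
    assert rec.volume_um3 == pytest.approx(truth.true_volume_um3)
    assert rec.branch_points == truth.branch_count
    assert rec.length_voxels > 0
    assert rec.mean_radius_voxels > 0
    assert rec.sholl is not None


def test_quantify_region_empty_mask():
    rec = quantify_region(_mask(np.zeros((8, 8, 8))))
    assert rec.volume_um3 == 0.0
    assert rec.branch_points == 0
    assert "empty-mask" in rec.flags
    assert np.isnan(rec.mean_radius_voxels)


def test_quantify_region_deterministic_after_identity_registration(small_tree):
    mask, _, _ = small_tree
    rec1 = quantify_region(mask, downsample_target=None, sample_id="a")
    moved = vq.apply_rigid(mask, vq.RigidTransform.identity(), "nearest")
    rec2 = quantify_region(moved, downsample_target=None, sample_id="a")
    assert rec1.as_row() == rec2.as_row()


def test_quantify_region_downsamples_wide_grids():
    m = np.zeros((9, 600, 600), np.uint8)
    m[2:7, 100:500, 290:311] = 1  # thick horizontal slab-tube along y
    rec = quantify_region(_mask(m), downsample_target=512)
    assert rec.volume_um3 == m.sum() * 1.0  # volume on full resolution
    assert rec.length_voxels > 0
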