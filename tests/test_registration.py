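"""Landmark and automatic rigid registration, resampling, PAM."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import vasquant as vq
from vasquant.registration import AutoRegParams


def _landmarks(rng, n=11):
    return vq.LandmarkSet([f"p{i}" for i in range(n)], rng.uniform(0, 100, (n, 3)))


def _apply(R, t, c, P):
    return (R @ (P - c).T).T + c + t


# ---------------------------------------------------------------------------
# landmark fit
# ---------------------------------------------------------------------------

def test_identity_fit(rng):
    lm = _landmarks(rng)
    xf, rms = vq.fit_landmark_rigid(lm, lm)
    assert rms < 1e-12
    assert np.allclose(xf.R, np.eye(3), atol=1e-12)
    assert np.allclose(xf.t, 0.0, atol=1e-12)


def test_known_transform_recovered(rng):
    lm = _landmarks(rng)
    R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    t = np.array([5.0, -3.0, 2.0])
    c = lm.points.mean(axis=0)
    target = vq.LandmarkSet(lm.names, _apply(R, t, c, lm.points))
    xf, rms = vq.fit_landmark_rigid(lm, target)
    assert rms <= 1e-9
    assert np.abs(xf.R - R).max() <= 1e-9
    assert np.allclose(xf.apply_points(lm.points), target.points, atol=1e-9)


def test_fit_rejects_degenerate_configurations(rng):
    two = vq.LandmarkSet(["a", "b"], rng.random((2, 3)))
    with pytest.raises(ValueError):
        vq.fit_landmark_rigid(two, two)
    line = vq.LandmarkSet(
        ["a", "b", "c", "d"], np.outer(np.arange(4.0), np.array([1.0, 2.0, 3.0]))
    )
    with pytest.raises(ValueError, match="collinear"):
        vq.fit_landmark_rigid(line, line)
    named = _landmarks(rng, 4)
    renamed = vq.LandmarkSet(list(reversed(named.names)), named.points)
    with pytest.raises(ValueError, match="names"):
        vq.fit_landmark_rigid(named, renamed)


def test_fit_invariant_to_common_rigid_motion(rng):
    """Moving both sets by the same rigid motion leaves the residual exact."""
    lm = _landmarks(rng)
    R = Rotation.from_euler("zyx", [20, -10, 35], degrees=True).as_matrix()
    t = np.array([3.0, 7.0, -4.0])
    q = vq.LandmarkSet(lm.names, lm.points + rng.normal(0, 1, lm.points.shape))
    _, rms0 = vq.fit_landmark_rigid(lm, q)
    moved_m = vq.LandmarkSet(lm.names, _apply(R, t, np.zeros(3), lm.points))
    moved_q = vq.LandmarkSet(lm.names, _apply(R, t, np.zeros(3), q.points))
    _, rms1 = vq.fit_landmark_rigid(moved_m, moved_q)
    assert np.isclose(rms0, rms1, atol=1e-9)


def test_noise_residual_matches_monte_carlo_expectation(rng):
    """With target noise σ per coordinate, the residual after removing the 6
    rigid dof satisfies E[Σ‖r‖²] = σ²(3N−6); check the MC mean RMS."""
    n, sigma, reps = 11, 1.0, 500
    base = _landmarks(rng, n)
    expected_rms = sigma * np.sqrt(3 * (n - 2) / n)
    rmss = []
    for _ in range(reps):
        noisy = vq.LandmarkSet(base.names, base.points + rng.normal(0, sigma, (n, 3)))
        _, rms = vq.fit_landmark_rigid(base, noisy)
        rmss.append(rms)
    assert abs(np.mean(rmss) - expected_rms) / expected_rms < 0.2


# ---------------------------------------------------------------------------
# apply_rigid
# ---------------------------------------------------------------------------

def test_apply_identity_is_identity(small_tree):
    mask, _, _ = small_tree
    out = vq.apply_rigid(mask, vq.RigidTransform.identity(), "nearest")
    assert np.array_equal(out.data, mask.data)


def test_integer_translation_nearest_is_exact(rng):
    data = (rng.random((12, 14, 16)) > 0.7).astype(np.uint8)
    mask = vq.BinaryMask(data, (2.0, 1.0, 1.0))
    # shift by (dz, dy, dx) = (2, -3, 4) voxels in physical µm
    t_xyz = np.array([4 * 1.0, -3 * 1.0, 2 * 2.0])
    xf = vq.RigidTransform(np.eye(3), t_xyz, np.zeros(3))
    out = vq.apply_rigid(mask, xf, "nearest")
    # out(z, y, x) = in(z-2, y+3, x-4)
    expected = np.zeros_like(data)
    expected[2:, : 14 - 3, 4:] = data[:-2, 3:, : 16 - 4]
    assert np.array_equal(out.data, expected)


def test_composition_of_transforms(rng):
    data = np.zeros((24, 24, 24))
    data[8:16, 8:16, 8:16] = rng.random((8, 8, 8))
    grid = vq.VoxelGrid(data, (1, 1, 1))
    c = np.array([11.5, 11.5, 11.5])
    xf1 = vq.RigidTransform(
        Rotation.from_euler("z", 15, degrees=True).as_matrix(), np.array([1.0, 0, 0]), c
    )
    xf2 = vq.RigidTransform(
        Rotation.from_euler("y", -10, degrees=True).as_matrix(), np.array([0, 2.0, 0]), c
    )
    seq = vq.apply_rigid(vq.apply_rigid(grid, xf1), xf2)
    combined = vq.apply_rigid(grid, xf2.compose(xf1))
    # one extra linear interpolation of tolerance
    assert np.abs(seq.data - combined.data).max() < 0.25


def test_unknown_interpolation_rejected(small_tree):
    mask, _, _ = small_tree
    with pytest.raises(ValueError):
        vq.apply_rigid(mask, vq.RigidTransform.identity(), "cubic")


def test_rigid_transform_invariants():
    with pytest.raises(ValueError):
        vq.RigidTransform(np.eye(3) * 2.0, np.zeros(3), np.zeros(3))
    with pytest.raises(ValueError):
        vq.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3), np.zeros(3))


# ---------------------------------------------------------------------------
# automatic registration (small, coarse settings; full-scale in acceptance)
# ---------------------------------------------------------------------------

def _fast_params():
    return AutoRegParams(
        n_orientations_kept=3, downsample_factors=(4, 2), angular_grid_step=90.0
    )


def test_self_registration_is_identity(small_tree):
    mask, _, _ = small_tree
    res = vq.register_automatic_rigid(mask, mask, _fast_params())
    assert not res.low_confidence
    ang = Rotation.from_matrix(res.transform.R).magnitude() * 180 / np.pi
    assert ang <= 0.5
    shift_vox = np.abs(res.transform.t) / np.array(mask.spacing)[::-1]
    assert shift_vox.max() <= 0.5
    reg = vq.apply_rigid(mask, res.transform, "nearest")
    assert vq.dice_coefficient(reg, mask) >= 0.99


def test_disjoint_structures_flag_low_confidence():
    """A thin line cannot overlap a large plate: Dice is bounded well below
    the confidence threshold and the result must be flagged."""
    a = np.zeros((24, 48, 48), np.uint8)
    a[12, 4:44, 12] = 1  # 40-voxel line
    b = np.zeros((24, 48, 48), np.uint8)
    b[6:18, 10:38, 20:44] = 1  # 8064-voxel block
    res = vq.register_automatic_rigid(
        vq.BinaryMask(a, (1, 1, 1)), vq.BinaryMask(b, (1, 1, 1)), _fast_params()
    )
    assert res.low_confidence


def test_empty_inputs_rejected(small_tree):
    mask, _, _ = small_tree
    empty = vq.BinaryMask(np.zeros_like(mask.data), mask.spacing)
    with pytest.raises(ValueError):
        vq.register_automatic_rigid(empty, mask, _fast_params())


# ---------------------------------------------------------------------------
# population average map
# ---------------------------------------------------------------------------

def test_pam_of_identical_masks_is_the_mask(small_tree):
    mask, _, _ = small_tree
    pam = vq.build_population_average_map([mask] * 6, "t")
    assert pam.n_samples == 6
    assert np.array_equal(pam.mean_map, mask.data.astype(float))


def test_pam_half_overlap_counts():
    a = np.zeros((2, 2, 4), np.uint8)
    a[..., :2] = 1
    b = np.zeros((2, 2, 4), np.uint8)
    b[..., 1:3] = 1
    pam = vq.build_population_average_map(
        [vq.BinaryMask(a, (1, 1, 1)), vq.BinaryMask(b, (1, 1, 1))], "t"
    )
    assert set(np.unique(pam.mean_map)) == {0.0, 0.5, 1.0}
    counts = pam.mean_map * pam.n_samples
    assert np.array_equal(counts, a.astype(float) + b)


def test_pam_conservation_property(rng):
    masks = [
        vq.BinaryMask((rng.random((4, 5, 6)) > 0.5).astype(np.uint8), (1, 1, 1))
        for _ in range(5)
    ]
    pam = vq.build_population_average_map(masks, "t")
    assert np.isclose(
        pam.mean_map.mean(), np.mean([m.data.mean() for m in masks])
    )


def test_pam_errors():
    with pytest.raises(ValueError):
        vq.build_population_average_map([], "t")
    a = vq.BinaryMask(np.zeros((2, 2, 2), np.uint8), (1, 1, 1))
    b = vq.BinaryMask(np.zeros((2, 2, 3), np.uint8), (1, 1, 1))
    with pytest.raises(ValueError):
        vq.build_population_average_map([a, b], "t")
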