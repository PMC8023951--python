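"""Point-set and masked-intensity rigid registration."""

import dataclasses

import numpy as np
import pytest

from ctmigrate import (
    BeadSet,
    PhantomSpec,
    RegistrationSettings,
    RigidTransform,
    common_region_mask,
    generate_phantom,
    match_beads,
    register_masked,
    register_points,
    simulate_double_exam,
    verify_registration,
)
from ctmigrate.errors import (
    DegenerateGeometryError,
    InsufficientCorrespondenceError,
    InsufficientOverlapError,
)
from ctmigrate.migration import MeasureConfig, _bone_reference_mask

from conftest import rand_rigid
from _oracles import brute_force_rigid_rms


def _bead_set(points):
    points = np.asarray(points, float)
    return BeadSet(points, np.full(len(points), 5), np.full(len(points), 3000.0),
                   1000.0)


# --------------------------------------------------------------------- #
# point-set superposition
# --------------------------------------------------------------------- #
def test_identical_point_sets_give_identity():
    pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0]])
    T, q = register_points(pts, pts)
    assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(T.translation, 0, atol=1e-12)
    assert q.rms_residual == pytest.approx(0.0, abs=1e-12)
    assert q.status == "green"


def test_constructed_transform_recovered_exactly():
    pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0]])
    true = RigidTransform.from_axis_angle([0, 0, 1], 10.0,
                                          translation=(1.0, 2.0, 3.0))
    T, q = register_points(pts, true.apply(pts))
    assert np.abs(T.rotation - true.rotation).max() < 1e-9
    assert np.abs(T.translation - true.translation).max() < 1e-9


def test_partial_correspondence_uses_only_listed_pairs():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(6, 3)) * 20
    true = rand_rigid(rng, 20, 10)
    b = np.vstack([true.apply(a[:4]), rng.normal(size=(2, 3)) * 100])
    T, _ = register_points(a, b, correspondence=[(i, i) for i in range(4)])
    assert np.abs(T.rotation - true.rotation).max() < 1e-9


def test_fewer_than_three_pairs_degenerate():
    a = np.array([[0, 0, 0], [1, 0, 0.0]])
    with pytest.raises(DegenerateGeometryError):
        register_points(a, a)


def test_collinear_points_degenerate():
    a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
    with pytest.raises(DegenerateGeometryError, match="collinear"):
        register_points(a, a + 1.0)


def test_noisy_fit_matches_brute_force_oracle():
    """The closed-form solution attains the brute-force SE(3) optimum."""
    rng = np.random.default_rng(42)
    a = rng.normal(size=(5, 3)) * 15
    true = rand_rigid(rng, 15, 5)
    b = true.apply(a) + rng.normal(0, 0.3, (5, 3))
    T, q = register_points(a, b)
    oracle = brute_force_rigid_rms(a, b)
    assert q.rms_residual == pytest.approx(oracle, abs=1e-6)


# --------------------------------------------------------------------- #
# bead matching
# --------------------------------------------------------------------- #
def test_exactly_mapped_beads_all_match_in_order():
    rng = np.random.default_rng(4)
    a = _bead_set(rng.normal(size=(6, 3)) * 20)
    T = rand_rigid(rng, 10, 5)
    b = _bead_set(T.apply(a.centroids))
    pairs = match_beads(a, b, initial=T, max_distance=1.0)
    assert pairs == [(i, i) for i in range(6)]


def test_missing_bead_drops_to_partial_match():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(6, 3)) * 20
    a = _bead_set(pts)
    b = _bead_set(pts[:-1])  # one bead occluded in the second exam
    pairs = match_beads(a, b, max_distance=1.0)
    assert len(pairs) == 5


def test_contested_target_keeps_only_mutual_pair():
    a = _bead_set([[0, 0, 0], [0, 0, 0.8], [10, 0, 0], [0, 10, 0]])
    b = _bead_set([[0, 0, 0.1], [10, 0, 0], [0, 10, 0]])
    pairs = match_beads(a, b, max_distance=2.0)
    matched_a = {i for i, _ in pairs}
    assert (0 in matched_a) != (1 in matched_a)  # only one of the rivals
    assert len(pairs) == 3


def test_too_few_matches_raises():
    a = _bead_set([[0, 0, 0], [5, 0, 0], [0, 5, 0]])
    b = _bead_set([[100, 100, 100], [105, 100, 100], [100, 105, 100]])
    with pytest.raises(InsufficientCorrespondenceError):
        match_beads(a, b, max_distance=2.0)


# --------------------------------------------------------------------- #
# masked intensity registration
# --------------------------------------------------------------------- #
def test_identical_volumes_register_to_identity(phantom64):
    vol, _ = phantom64
    mask = _bone_reference_mask(vol, MeasureConfig())
    T, q = register_masked(vol, vol, mask)
    assert np.linalg.norm(T.translation) < 1e-3
    assert T.rotation_angle_deg < 1e-3
    assert q.status == "green"
    assert q.fraction_within_tol == pytest.approx(1.0)


def test_integer_voxel_shift_recovered(spec64_clean):
    vol, _ = generate_phantom(spec64_clean)
    shift_vox = np.array([3, -2, 1])
    moved = np.roll(vol.voxels, shift_vox, axis=(0, 1, 2))
    import ctmigrate

    vol_b = ctmigrate.CTVolume(moved, vol.spacing, vol.origin, vol.direction)
    # rolling content by +k voxels moves the anatomy +k voxels in world
    true_t = shift_vox * vol.spacing
    mask = _bone_reference_mask(vol, MeasureConfig())
    T, _ = register_masked(vol, vol_b, mask)
    assert np.abs(T.translation - true_t).max() < 1e-2 * 0.6
    assert T.rotation_angle_deg < 1e-2


def test_subvoxel_translation_recovered(spec96_clean):
    spec = dataclasses.replace(spec96_clean, blur_sigma=0.6)
    true = RigidTransform(np.eye(3), [0.15, 0.15, 0.15])  # 0.25 voxel
    e1, e2, _ = simulate_double_exam(spec, true, RigidTransform.identity(),
                                     seeds=(3, 3))
    mask = _bone_reference_mask(e1, MeasureConfig())
    T, _ = register_masked(e1, e2, mask)
    assert np.abs(T.translation - true.translation).max() < 0.1 * 0.6


def test_empty_mask_rejected(phantom64):
    vol, _ = phantom64
    from ctmigrate.segmentation import BinaryMask

    empty = BinaryMask.like(vol, np.zeros(vol.shape, bool))
    with pytest.raises(DegenerateGeometryError):
        register_masked(vol, vol, empty)


# --------------------------------------------------------------------- #
# common region and verification
# --------------------------------------------------------------------- #
def test_identical_volumes_keep_full_common_region(phantom64):
    vol, _ = phantom64
    mask = _bone_reference_mask(vol, MeasureConfig())
    common = common_region_mask(vol, vol, RigidTransform.identity(), mask,
                                residual_hu=150.0)
    assert np.array_equal(common.mask, mask.mask)


def test_carved_cavity_excluded_from_common_region(phantom64):
    """Simulated osteolysis: bone voxels replaced by background in the
    second exam must drop out of the common region."""
    vol, truth = phantom64
    import ctmigrate

    carved = vol.voxels.copy()
    center = truth.bead_positions_bone[0]  # a point inside the bone wall
    idx = np.argwhere(np.ones(vol.shape, bool))
    w = vol.index_to_world(idx)
    hole = np.linalg.norm(w - center, axis=1) < 4.0
    carved.ravel()[np.flatnonzero(hole)] = -50.0
    vol_b = ctmigrate.CTVolume(carved, vol.spacing, vol.origin, vol.direction)
    mask = _bone_reference_mask(vol, MeasureConfig())
    common = common_region_mask(vol, vol_b, RigidTransform.identity(), mask,
                                residual_hu=150.0)
    in_mask = mask.mask.ravel() & hole
    excluded = in_mask & ~common.mask.ravel()
    assert in_mask.sum() > 50
    assert excluded.sum() >= 0.9 * in_mask.sum()


def test_zero_residual_tolerance_on_noise_raises_overlap_error(phantom64):
    vol, _ = phantom64
    rng = np.random.default_rng(0)
    import ctmigrate

    vol_b = ctmigrate.CTVolume(
        vol.voxels + rng.normal(0, 20, vol.shape).astype(np.float32),
        vol.spacing, vol.origin, vol.direction)
    mask = _bone_reference_mask(vol, MeasureConfig())
    with pytest.raises(InsufficientOverlapError):
        common_region_mask(vol, vol_b, RigidTransform.identity(), mask,
                           residual_hu=0.0)


def test_verification_green_on_identity_red_on_gross_offset(phantom64):
    vol, _ = phantom64
    mask = _bone_reference_mask(vol, MeasureConfig())
    good = verify_registration(vol, vol, RigidTransform.identity(), mask,
                               tol_hu=60.0)
    assert good.status == "green" and good.fraction_within_tol == 1.0
    bad = verify_registration(
        vol, vol, RigidTransform(np.eye(3), [10.0, 0, 0]), mask, tol_hu=60.0)
    assert bad.status == "red"
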