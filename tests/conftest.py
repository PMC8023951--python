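"""Shared fixtures: small phantoms generated once per session."""

import numpy as np
import pytest

from ctmigrate import (
    MeasureConfig,
    PhantomSpec,
    RigidTransform,
    generate_phantom,
    simulate_double_exam,
)


@pytest.fixture(scope="session")
def spec64():
    """Fast 64^3 phantom: bone beads only (the cup interior at this scale
    is too small to host beads at the required cement clearance)."""
    return PhantomSpec.scaled_default(
        (64,) * 3, n_bone_beads=6, n_implant_beads=0)


@pytest.fixture(scope="session")
def spec64_clean(spec64):
    import dataclasses

    return dataclasses.replace(spec64, noise_sigma=0.0)


@pytest.fixture(scope="session")
def spec96_clean():
    return PhantomSpec.scaled_default((96,) * 3, noise_sigma=0.0)


@pytest.fixture(scope="session")
def phantom64(spec64):
    return generate_phantom(spec64)


@pytest.fixture(scope="session")
def phantom64_clean(spec64_clean):
    return generate_phantom(spec64_clean)


@pytest.fixture(scope="session")
def phantom96_clean(spec96_clean):
    return generate_phantom(spec96_clean)


@pytest.fixture(scope="session")
def pair96():
    """One default-noise 96^3 double examination with zero migration and a
    known repositioning, shared by integration tests."""
    spec = PhantomSpec.scaled_default((96,) * 3)
    repo = RigidTransform.from_axis_angle(
        [0.2, 1.0, 0.4], 1.2, translation=(2.0, -1.5, 1.0))
    exam1, exam2, truth = simulate_double_exam(
        spec, repo, RigidTransform.identity(), seeds=(101, 102))
    return spec, exam1, exam2, truth


@pytest.fixture()
def default_config():
    return MeasureConfig()


def rand_rigid(rng, max_rot_deg=30.0, max_trans=20.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return RigidTransform.from_axis_angle(
        axis, rng.uniform(-max_rot_deg, max_rot_deg),
        translation=rng.uniform(-max_trans, max_trans, 3))
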