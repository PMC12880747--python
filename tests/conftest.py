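import numpy as np
import pytest

from sceneenc.gabor import GaborBankSpec, build_gabor_bank, gabor_feature_matrix
from sceneenc.surface import fit_distance_bins, surface_feature_matrix
from sceneenc.synth import (
    PlaneSpec,
    SceneSample,
    SceneSpec,
    StimulusSet,
    generate_scene,
    generate_stimulus_set,
)


def make_sample(depth, normals, valid=None, image=None) -> SceneSample:
    """Hand-built SceneSample for oracle tests."""
    depth = np.asarray(depth, dtype=float)
    normals = np.asarray(normals, dtype=float)
    if valid is None:
        valid = np.ones(depth.shape, dtype=bool)
    if image is None:
        image = np.full(depth.shape, 0.5)
    return SceneSample(image=image, depth=depth, normals=normals, valid_mask=valid)


def flat_scene_spec(depth=2.0, direction="forward", invalid_fraction=0.0, **kw):
    """Single full-frame plane at constant (or ramped) distance."""
    return SceneSpec(
        planes=(PlaneSpec(direction, (0.0, 1.0, 0.0, 1.0), (depth, depth), **kw),),
        invalid_fraction=invalid_fraction,
    )


@pytest.fixture(scope="session")
def stimset():
    return generate_stimulus_set(12, seed=7)


@pytest.fixture(scope="session")
def bins(stimset):
    return fit_distance_bins(stimset, seed=0)


@pytest.fixture(scope="session")
def gabor_bank():
    return build_gabor_bank(GaborBankSpec(), resolution=(64, 64))


@pytest.fixture(scope="session")
def gabor_features(stimset, gabor_bank):
    return gabor_feature_matrix(stimset, gabor_bank)


@pytest.fixture(scope="session")
def global_features(stimset, bins):
    return surface_feature_matrix(stimset, bins, "global")


@pytest.fixture(scope="session")
def quadrant_features(stimset, bins):
    return surface_feature_matrix(stimset, bins, "quadrant")
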