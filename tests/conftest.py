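"""Shared fixtures: small phantoms and preprocessed cases, built once."""

import warnings

import numpy as np
import pytest

from ctaseg.phantom import PhantomSpec, generate_phantom
from ctaseg.preprocessing import PreprocessConfig, preprocess_case

# registration emits convergence warnings on tiny grids; tests that care
# about them assert explicitly
warnings.filterwarnings("ignore", message="rigid registration")

SMALL_GRID = dict(grid_shape=(40, 48, 32), spacing_mm=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(**SMALL_GRID, pose_perturbation=(1.0, 1.0), seed=20)


@pytest.fixture(scope="session")
def lesioned_case(small_spec):
    return generate_phantom(small_spec, case_id="A-fix", group="A")


@pytest.fixture(scope="session")
def confounder_case(small_spec):
    from dataclasses import replace

    spec = replace(small_spec, lesion_present=False, seed=21)
    return generate_phantom(spec, case_id="B-fix", group="B")


@pytest.fixture(scope="session")
def preprocess_config():
    return PreprocessConfig(target_spacing_mm=2.0, crop_margin_voxels=2)


@pytest.fixture(scope="session")
def preprocessed_pair(lesioned_case, confounder_case, preprocess_config):
    """One lesioned + one confounder-only case, fully conditioned (cta+hemi)."""
    return [
        preprocess_case(c, preprocess_config, channels=("cta", "hemi"))
        for c in (lesioned_case, confounder_case)
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
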