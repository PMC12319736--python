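import numpy as np
import pytest

from templateica import synthetic
from templateica.types import GroupMaps


@pytest.fixture(scope="session")
def sphere_mesh():
    return synthetic.make_mesh(300, "sphere", seed=11)


@pytest.fixture(scope="session")
def grid_mesh():
    return synthetic.make_mesh(100, "grid", seed=0)


@pytest.fixture(scope="session")
def small_truth(sphere_mesh):
    """Moderate-noise cohort used by several downstream tests."""
    return synthetic.sample_truth(
        sphere_mesh, n_subjects=20, n_ics=4, n_timepoints=200,
        noise_sd=2.0, age_effect=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def group_maps(small_truth):
    return GroupMaps(maps=small_truth.group_maps)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
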