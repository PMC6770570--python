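import numpy as np
import pytest

from encompass.synthgen import (
    SynthSpec,
    make_complex_trajectory,
    make_conformer_ensemble,
    make_pose_set,
)


@pytest.fixture(scope="session")
def small_pose_data():
    """40-pose synthetic set with 25% planted productive poses."""
    return make_pose_set(
        SynthSpec(seed=11, n_poses=40, productive_fraction=0.25)
    )


@pytest.fixture(scope="session")
def small_ensemble():
    return make_conformer_ensemble(SynthSpec(seed=7, n_conformers=12))


@pytest.fixture(scope="session")
def short_trajectory():
    return make_complex_trajectory(
        SynthSpec(seed=13, trajectory_length=100)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
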