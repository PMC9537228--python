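import numpy as np
import pytest

from gaitstream import (
    GaitSimParams,
    MotionSample,
    NormalizationConfig,
    default_skeleton,
    generate_cohort,
    normalize,
)


@pytest.fixture(scope="session")
def skeleton():
    return default_skeleton()


@pytest.fixture(scope="session")
def sim_params():
    return GaitSimParams()


@pytest.fixture(scope="session")
def small_cohort(sim_params):
    """Five samples, all four classes represented."""
    counts = {
        "healthy": 2,
        "joint_problem": 1,
        "muscle_weakness": 1,
        "neurological_defect": 1,
    }
    return generate_cohort(sim_params, counts, seed=123)


@pytest.fixture(scope="session")
def normalized_sample(small_cohort):
    return normalize(small_cohort[0], NormalizationConfig(t_target=100))


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def make_sample(positions, skeleton=None, **kwargs):
    """Helper for hand-built motions."""
    from gaitstream import default_skeleton

    return MotionSample(
        positions=np.asarray(positions, dtype=float),
        skeleton=skeleton or default_skeleton(),
        **kwargs,
    )
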