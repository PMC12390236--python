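import numpy as np
import pytest

from pdsense import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny complete cohort (no missing blocks, reduced grid) shared by
    structural tests."""
    config = SyntheticConfig(
        n_patients=4,
        seed=7,
        hands=("right",),
        exercises=(1, 3),
        missing_block_probability=0.0,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def sample_recording(small_cohort):
    exam = small_cohort.examinations[0]
    return exam.recordings[("phone", "accelerometer", "right", 1)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
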