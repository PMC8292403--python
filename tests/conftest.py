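import numpy as np
import pytest

from gravisyn import synthetic

GRAVITY_LABELS = ["1g", "0.6g", "0.38g", "0.16g", "0.07g"]
PROFILE_KINDS = ["constant", "linear_decreasing", "threshold_decreasing", "u_shaped"]


@pytest.fixture(scope="session")
def gravity_labels():
    return list(GRAVITY_LABELS)


@pytest.fixture(scope="session")
def profile_kinds():
    return list(PROFILE_KINDS)


@pytest.fixture(scope="session")
def default_gt():
    """A 4-module / 5-gravity / 9-participant ground truth with mild noise."""
    return synthetic.make_ground_truth(
        4, GRAVITY_LABELS, PROFILE_KINDS, seed=1, noise_sd=0.02
    )


@pytest.fixture(scope="session")
def noiseless_gt():
    """Same structure, no noise and no participant variability."""
    return synthetic.make_ground_truth(
        4, GRAVITY_LABELS, PROFILE_KINDS, seed=1,
        noise_sd=0.0, participant_sigma=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
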