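import numpy as np
import pytest

from supplygame import baseline, sample_scenarios


@pytest.fixture(scope="session")
def baseline_p():
    return baseline()


@pytest.fixture(scope="session")
def scenarios():
    """A reusable batch of random valid parameter sets."""
    return sample_scenarios(n=100, seed=20259, enforce="none")


@pytest.fixture(scope="session")
def bistable_scenarios():
    """Scenarios satisfying both stability condition sets."""
    return sample_scenarios(n=60, seed=7, enforce="both")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_states(rng, n, margin=0.0):
    """n random states in the (optionally shrunken) unit cube."""
    return rng.uniform(margin, 1.0 - margin, size=(n, 3))
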