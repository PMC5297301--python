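import numpy as np
import pytest

from migasel import SimConfig, Trial, TrialSet, generate_trialset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_trialset(rng):
    """Two random 1152 x 3 trials, one per class."""
    trials = [Trial(rng.standard_normal((1152, 3))) for _ in range(2)]
    return TrialSet(trials, ["left", "right"], 128.0)


@pytest.fixture(scope="session")
def simulated_trialset():
    """A small simulated session shared by the slower pipeline tests."""
    return generate_trialset(SimConfig(n_trials=8, seed=42))
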