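import numpy as np
import pytest

from camtrigger import (
    DEFAULT_DETECTION_SPEC,
    default_simulation_config,
    simulate_trials,
)


@pytest.fixture(scope="session")
def sim_frame():
    """Small covariate-mode synthetic dataset (3 replicates, 1134 trials)."""
    return simulate_trials(default_simulation_config(seed=7, replicates=3))


@pytest.fixture(scope="session")
def detection_mode_frame():
    """Trials whose outcomes come from the detection function alone."""
    cfg = default_simulation_config(seed=11, replicates=3)
    cfg.coefficients = None
    return simulate_trials(cfg)


@pytest.fixture(scope="session")
def true_detfun():
    return DEFAULT_DETECTION_SPEC


@pytest.fixture
def rng():
    return np.random.default_rng(42)
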