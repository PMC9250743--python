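import numpy as np
import pytest

from repanom.pipeline import PipelineConfig, fit_exercise_model
from repanom.simulate import SimConfig, generate_session


@pytest.fixture(scope="session")
def clean_config():
    """Noise-light configuration without pauses: ground truth is sharp."""
    return SimConfig(pause_probability=0.0, noise_sd=0.01)


@pytest.fixture(scope="session")
def clean_model(clean_config):
    """Exercise model fitted on three clean training sessions (PCA phase
    extractor; shared across tests that only need a working model)."""
    train = [
        generate_session(clean_config, f"S{i}", i).features for i in range(3)
    ]
    return fit_exercise_model(train, PipelineConfig(), seed=0)


@pytest.fixture(scope="session")
def clean_session(clean_config):
    return generate_session(clean_config, "T", 99)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
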