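import numpy as np
import pytest

from pulseoxmc import experiment_pipeline as pipeline
from pulseoxmc.tissue_model import (
    HemodynamicState,
    build_finger_model,
    make_homogeneous_phantom,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240813)


@pytest.fixture(scope="session")
def finger_light_diastole():
    return build_finger_model("light", HemodynamicState(0.90, "diastole"))


@pytest.fixture(scope="session")
def absorbing_phantom():
    """Index-matched pure absorber: transmittance exp(-mu_a * L) exactly."""
    return make_homogeneous_phantom(1.0, 0.0, 0.0, 1.0, index=1.0)


@pytest.fixture(scope="session")
def scaled_down_experiment():
    """Full 84-condition grid at the scaled-down budget (1e4 detected)."""
    config = pipeline.ExperimentConfig.from_preset("ci", seed=1)
    raw = pipeline.run_grid(config)
    return pipeline.assemble_tables(raw, config)
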