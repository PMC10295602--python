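import numpy as np
import pytest

from vesselseg.synthetic import VesselSimConfig, generate_sample


@pytest.fixture(scope="session")
def small_sim_config() -> VesselSimConfig:
    return VesselSimConfig(image_size=(64, 64), n_trees=2, branch_depth=3, seed=0)


@pytest.fixture(scope="session")
def vessel_sample(small_sim_config):
    return generate_sample(small_sim_config, 0)


@pytest.fixture(scope="session")
def train_samples(small_sim_config):
    """Eight 64x64 synthetic samples — the overfit fixture."""
    return [generate_sample(small_sim_config, i) for i in range(8)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
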