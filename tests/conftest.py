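import numpy as np
import pytest

from crowlaw.menzerath import MenzerathParams
from crowlaw.synthetic import GeneratorConfig, generate_dataset, model_frame


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset reused across read-only tests."""
    config = GeneratorConfig(
        seed=42,
        groups_per_population=2,
        individuals_per_group=4,
        sequences_per_individual=15,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def small_frame(small_dataset):
    return model_frame(small_dataset, segmented=False)


@pytest.fixture
def noiseless_config():
    """Law y = x^-0.5 with every random effect switched off."""
    return GeneratorConfig(
        seed=0,
        law=MenzerathParams(a=1.0, b=-0.5, c=0.0),
        sd_population=0.0,
        sd_group=0.0,
        sd_individual=0.0,
        sd_sequence=0.0,
        sd_residual=0.0,
        singleton_fraction=0.0,
        sequences_per_individual=5,
        groups_per_population=1,
        individuals_per_group=3,
        n_populations=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
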