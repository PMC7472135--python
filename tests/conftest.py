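import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

from pearnose import SimulationConfig, assemble_feature_table, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_train_table():
    """3 fruit per grade, well separated: 18 curves -> 1080 feature rows."""
    cfg = SimulationConfig(seed=7, n_per_class=(3,) * 6)
    return assemble_feature_table(generate_cohort(cfg))


@pytest.fixture(scope="session")
def tiny_test_table():
    cfg = SimulationConfig(seed=8, n_per_class=(2,) * 6)
    return assemble_feature_table(generate_cohort(cfg))
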