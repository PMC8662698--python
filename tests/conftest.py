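import numpy as np
import pytest
from hypothesis import settings

from personasim.core import PersonalityCategory, default_config, load_parameters

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

CATEGORIES = list(PersonalityCategory)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def all_params(config):
    """(affect, face, gaze, gesture) parameter tuples for every category."""
    return {cat: load_parameters(cat, config) for cat in CATEGORIES}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
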