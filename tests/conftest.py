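import numpy as np
import pytest

from hetpop import AnalysisConfig, GeneratorConfig, generate_session
from hetpop.pipeline import preprocess_session


@pytest.fixture(scope="session")
def small_session():
    """One modest synthetic session shared by read-only tests."""
    cfg = GeneratorConfig(n_neurons=24, n_blocks=2, seed=11)
    session, truth = generate_session(cfg)
    return session, truth


@pytest.fixture(scope="session")
def small_prep(small_session):
    session, _ = small_session
    return preprocess_session(
        session, AnalysisConfig(baseline_stride=8, rng_seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
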