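import numpy as np
import pytest

from rrcl import SimConfig, GroundTruth, build_scheme, code_study, generate_study


@pytest.fixture(scope="session")
def scheme1():
    return build_scheme(1, 0.8)


@pytest.fixture(scope="session")
def scheme2():
    return build_scheme(2, 0.8)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared across test modules."""
    cfg = SimConfig(n_participants=6, n_blocks=2, n_practice=10, n_test=150, seed=42)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_coded(small_study):
    return code_study(small_study)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
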