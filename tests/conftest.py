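import numpy as np
import pytest

from ledcens import LEDParams, make_scheme_I, simulate_iatii
from ledcens.datasets import rme_data, table4_sample


@pytest.fixture(scope="session")
def rme():
    return rme_data()


@pytest.fixture(scope="session")
def sample_A():
    return table4_sample("A")


@pytest.fixture(scope="session")
def sample_B():
    return table4_sample("B")


@pytest.fixture(scope="session")
def sample_C():
    return table4_sample("C")


@pytest.fixture(scope="session")
def case_samples(sample_A, sample_B, sample_C):
    """One sample per censoring case: simulated case I plus fixtures (II, III)."""
    scheme = make_scheme_I(30, 15, 5.0, 9.0)  # generous thresholds: case I
    case_I = simulate_iatii(LEDParams(1.5, 1.2), scheme, seed=42)
    assert case_I.case == "I"
    return {"I": case_I, "II": sample_B, "III": sample_A}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240516)
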