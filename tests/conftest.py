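import numpy as np
import pytest

from hicdyn.synthetic import default_fixture_spec, make_tad_model, random_valid_k


@pytest.fixture(scope="session")
def tad_k():
    """Ground-truth N=60 spring matrix: backbone + two TAD blocks + a loop."""
    return make_tad_model(default_fixture_spec())


@pytest.fixture(scope="session")
def tad_contacts(tad_k):
    from hicdyn.mapping import forward_map

    return forward_map(tad_k)


@pytest.fixture
def dimer_k():
    return np.array([[0.0, 1.0], [1.0, 0.0]])


@pytest.fixture(scope="session")
def small_random_k():
    return random_valid_k(10, seed=42)
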