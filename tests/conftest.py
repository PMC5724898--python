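import pytest

import strident as st


@pytest.fixture(scope="session")
def betaIG():
    return st.load_circuit("betaIG")


@pytest.fixture(scope="session")
def hormone():
    return st.load_circuit("hormone_nonlinear")


@pytest.fixture(scope="session")
def toy_product():
    return st.load_circuit("toy_product")


@pytest.fixture(scope="session")
def betaIG_steady(betaIG):
    return st.find_steady_state(betaIG)
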