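import pytest

from syntherm import ThermoConditions, load_network


@pytest.fixture(scope="session")
def network():
    return load_network()


@pytest.fixture(scope="session")
def table(network):
    return network.table


@pytest.fixture(scope="session")
def reactions(network):
    return network.reactions


@pytest.fixture(scope="session")
def ref_dg(network):
    return network.reference_dg


@pytest.fixture(scope="session")
def cond():
    return ThermoConditions()
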