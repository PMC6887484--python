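import pytest

from dorsalhorn.canonical import canonical_neuron, canonical_rf


@pytest.fixture(scope="session")
def tonic_model():
    return canonical_neuron("inhibitory_tonic")


@pytest.fixture(scope="session")
def delayed_model():
    return canonical_neuron("excitatory_delayed")


@pytest.fixture(scope="session")
def single_model():
    return canonical_neuron("excitatory_single")


@pytest.fixture(scope="session")
def adapting_rf():
    return canonical_rf("adapting")


@pytest.fixture(scope="session")
def non_adapting_rf():
    return canonical_rf("non_adapting")
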