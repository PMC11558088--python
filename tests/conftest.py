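import pytest

from duplexml.descriptors import TermTable
from duplexml.energetics import generate_synthetic_energy_table
from duplexml.entropy import EntropyParams


@pytest.fixture(scope="session")
def term_table():
    return TermTable.default()


@pytest.fixture(scope="session")
def energy_table():
    return generate_synthetic_energy_table(seed=7)


@pytest.fixture(scope="session")
def entropy_params():
    return EntropyParams()
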