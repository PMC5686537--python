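import pytest

from evocode.codes import ChemicalClassTable, standard_code
from evocode.datagen import random_code


@pytest.fixture(scope="session")
def std():
    return standard_code()


@pytest.fixture(scope="session")
def classes():
    return ChemicalClassTable()


@pytest.fixture(scope="session")
def random_codes():
    """A reusable batch of scrambled valid codes."""
    return [random_code(seed) for seed in range(50)]
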