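import pytest

from nusimet.chem import NUSINERSEN
from nusimet.fixtures import metabolite_ion_table, metabolite_ions
from nusimet.fragments import default_candidate_space


@pytest.fixture(scope="session")
def candidate_space():
    """The default 2-4-mer candidate space of nusinersen (built once)."""
    return default_candidate_space(NUSINERSEN)


@pytest.fixture(scope="session")
def reference_ion_table():
    return metabolite_ion_table()


@pytest.fixture(scope="session")
def reference_ions():
    return metabolite_ions()
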