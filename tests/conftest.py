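import pytest

from aucbind import default_conditions, reference_species


@pytest.fixture(scope="session")
def species():
    return reference_species()


@pytest.fixture(scope="session")
def conditions():
    return default_conditions()
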