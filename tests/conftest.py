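import pytest

from dmnlkit.model import (
    SPECIES_TYPE,
    bothid_fixture,
    canonical_teleost_order,
)


@pytest.fixture(scope="session")
def canonical():
    return canonical_teleost_order()


@pytest.fixture(scope="session")
def fixtures():
    return {code: bothid_fixture(code) for code in SPECIES_TYPE}
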