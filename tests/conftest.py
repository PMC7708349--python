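import pytest

from kirmotif import canonical_library

#: reduced problem sizes so the whole suite runs in minutes on one CPU
TEST_PROBE_LENGTH = 40
TEST_SPACING = 120
TEST_MAX_COST = 5


@pytest.fixture(scope="session")
def lib():
    """Canonical synthetic world at test scale."""
    return canonical_library(seed=1, probe_length=TEST_PROBE_LENGTH,
                             spacing=TEST_SPACING)


@pytest.fixture(scope="session")
def alphabet(lib):
    return lib.alphabet


@pytest.fixture(scope="session")
def registry(lib):
    return lib.registry


@pytest.fixture(scope="session")
def definitions(lib):
    return lib.definitions
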