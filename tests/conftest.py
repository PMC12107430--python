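import pytest

from smarti.reference import LibraryDesign, study_designs
from smarti.simulate import AdapterSpec, synthetic_reference


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference(0)


@pytest.fixture(scope="session")
def designs():
    return study_designs()


@pytest.fixture(scope="session")
def adapter():
    return AdapterSpec()


@pytest.fixture
def toy_design(reference):
    """Four mutagenized positions with a modest doping rate."""
    return LibraryDesign("toy", ((6101, 6104),), 0.02)
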