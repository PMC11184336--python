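import pytest

from tnevolve import make_design, make_reference


@pytest.fixture(scope="session")
def small_reference():
    cds, protein = make_reference(50, seed=1)
    return cds, protein


@pytest.fixture(scope="session")
def small_design(small_reference):
    cds, _ = small_reference
    return make_design(cds, 10, seed=3)


@pytest.fixture(scope="session")
def full_reference():
    """Full transposase-scale reference (686 aa)."""
    cds, protein = make_reference(686, seed=7)
    return cds, protein


@pytest.fixture(scope="session")
def full_design(full_reference):
    cds, _ = full_reference
    return make_design(cds, 108, seed=3)
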