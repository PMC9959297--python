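import pytest

from tcrep.reference import synthetic_reference, toy_reference


@pytest.fixture(scope="session")
def full_ref():
    """Full murine gene-space synthetic reference (112/51/23/13 genes)."""
    return synthetic_reference()


@pytest.fixture(scope="session")
def toy_ref():
    """Small reference (8 TRAV, 6 TRAJ, 5 TRBV, 4 TRBJ) for alignment tests."""
    return toy_reference()
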