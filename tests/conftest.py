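import pytest
from hypothesis import settings

from mstnpop import em_phase, reconstruct_ucm_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ucm():
    """The reconstructed 54-animal, 9-locus cohort."""
    return reconstruct_ucm_fixture()


@pytest.fixture(scope="session")
def ucm_phased(ucm):
    """Default EM phasing of the cohort (parsimony refinement on)."""
    return em_phase(ucm)
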