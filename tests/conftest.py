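import pytest

from memtug import ModelParameters, get_profile


@pytest.fixture(scope="session")
def reduced_params() -> ModelParameters:
    """Reduced-unit double-well test set: energies in kBT, lengths in r_e
    units (D_e=1, r_e=1, beta=10, l0=2.2, d=3.0, H_B=1)."""
    return ModelParameters(D_e=1.0, r_e=1.0, beta=10.0, l0=2.2, d=3.0, H_B=1.0)


@pytest.fixture(scope="session")
def paper_params() -> ModelParameters:
    """Reference gramicidin/monoglyceride profile."""
    return get_profile("paper2011")
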