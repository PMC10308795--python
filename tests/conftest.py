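import numpy as np
import pytest

from mfa13.emu import TracerMixture
from mfa13.fixtures import toy_energy_model, toy_model, toy_reference_fluxes


@pytest.fixture(scope="session")
def toy():
    return toy_model()


@pytest.fixture(scope="session")
def toy_energy():
    return toy_energy_model()


@pytest.fixture()
def ref_fluxes(toy):
    return toy_reference_fluxes(toy)


@pytest.fixture()
def paper_mixture():
    """20 % [1-13C] + 80 % [2-13C] glycerol, the study's labelling design."""
    return TracerMixture({"GLYC": [((1,), 0.2), ((2,), 0.8)]})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
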