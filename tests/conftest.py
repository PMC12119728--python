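import numpy as np
import pytest

from neuropet.imaging import SubjectMeta
from neuropet.simulate import make_population_aif
from neuropet.simulate.pet import clinical_schedule


@pytest.fixture(scope="session")
def schedule():
    return clinical_schedule()


@pytest.fixture(scope="session")
def aif():
    return make_population_aif()


@pytest.fixture(scope="session")
def meta():
    return SubjectMeta(injected_activity_mbq=346.4, body_weight_kg=70.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
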