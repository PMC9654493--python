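import numpy as np
import pytest

from stairgait.contact import ContactParams
from stairgait.dynamics import PlanarEngine
from stairgait.model import planar_model


@pytest.fixture(scope="session")
def stair_engine():
    return PlanarEngine(planar_model("stairs"))


@pytest.fixture(scope="session")
def contact_params():
    return ContactParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
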