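import numpy as np
import pytest

from wristpet.phantom import build_forearm_phantom
from wristpet.scanner import CRYSTALS, build_wristpet1, build_wristpet2


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def forearm():
    return build_forearm_phantom()


@pytest.fixture(scope="session")
def bgo():
    return CRYSTALS["BGO"]


@pytest.fixture(scope="session")
def wristpet1_bgo():
    return build_wristpet1(CRYSTALS["BGO"])


@pytest.fixture(scope="session")
def wristpet2_bgo():
    return build_wristpet2(CRYSTALS["BGO"], 1)
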