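import numpy as np
import pytest

from rdnamap import RepeatCoordinateSystem, build_mef_scenario


@pytest.fixture(scope="session")
def mouse_cs() -> RepeatCoordinateSystem:
    """The BK000964v3 coordinate system with the EcoRI-displaced origin."""
    return RepeatCoordinateSystem()


@pytest.fixture(scope="session")
def wt_scenario():
    """One wild-type scenario shared across read-level tests."""
    return build_mef_scenario("WT", seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
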