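import pytest

from rbctweezer import CellOpticalGeometry, FluidConfig, OpticalConfig
from rbctweezer.synthetic import default_cohort_configs


@pytest.fixture(scope="session")
def defaults():
    return default_cohort_configs()


@pytest.fixture()
def optics():
    return OpticalConfig()


@pytest.fixture()
def fluid():
    return FluidConfig()


@pytest.fixture()
def geometry():
    return CellOpticalGeometry(radius=2e-6, trap_offset=0.5e-6)
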