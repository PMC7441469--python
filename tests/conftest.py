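import pytest

from cmro2map import GridSpec, sample_krogh_erlang_map
from cmro2map.presets import single_vessel_scenario


@pytest.fixture(scope="session")
def krogh_scenario():
    """Single central arteriole, uniform consumption M-hat = 1."""
    return single_vessel_scenario()


@pytest.fixture(scope="session")
def krogh_map_coarse(krogh_scenario):
    """Noise-free ground-truth map at the coarse 0.035 spacing."""
    return sample_krogh_erlang_map(krogh_scenario, GridSpec.centered(1.0, 0.035))


@pytest.fixture(scope="session")
def krogh_map_fine(krogh_scenario):
    """Noise-free ground-truth map at the standard 0.007 spacing."""
    return sample_krogh_erlang_map(krogh_scenario, GridSpec.centered(1.0, 0.007))
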