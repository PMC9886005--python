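import pytest
from hypothesis import settings

from loihimap import EXAMPLE_NEURONS, MappingConfig, frozen_spike_fixture

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def bias_params():
    """Worked parameter set driven by a 200 pA constant current."""
    return EXAMPLE_NEURONS["bias_driven"]


@pytest.fixture
def spike_params():
    """Worked parameter set driven by external spike trains (zero bias)."""
    return EXAMPLE_NEURONS["spike_driven"]


@pytest.fixture
def default_cfg():
    """The default mapping precision: 1 ms/step, 1e-4 mV/level."""
    return MappingConfig(V_s=1e-4, dt=1.0)


@pytest.fixture
def fixture_spikes():
    return frozen_spike_fixture()
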