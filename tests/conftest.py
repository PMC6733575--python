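import numpy as np
import pytest
from hypothesis import settings

# deterministic, CI-friendly hypothesis profile
settings.register_profile("default", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def regular_train():
    """Perfectly regular 100 Hz simple spikes with 1 Hz complex spikes."""
    from pcphys import SpikeTrain
    cs = np.arange(0.5, 10.0, 1.0)
    ss = np.arange(0.0, 10.0, 0.01)
    ss = ss[~np.isin(np.round(ss, 9), np.round(cs, 9))]
    return SpikeTrain(simple_spike_times=ss, complex_spike_times=cs,
                      duration=10.0)
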