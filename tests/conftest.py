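import numpy as np
import pytest
from hypothesis import settings

from synchain import NetworkConfig, make_fixture
from synchain.stimulus import StimulusConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def mini_record():
    """Miniature trained network (5 neurons, 200 afferents, 10 s)."""
    return make_fixture(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_stim_cfg():
    return StimulusConfig(n_afferents_total=200, n_pattern_afferents=100,
                          total_duration=10_000.0, seed=5)


@pytest.fixture()
def tiny_net_cfg():
    base = NetworkConfig()
    return base.with_(
        n_excitatory=5,
        stimulus=base.stimulus.with_(n_afferents_total=200, n_pattern_afferents=100),
        w_ff_max=4.5,
        train_duration=2_000.0,
        checkpoint_interval=1_000.0,
        seed=7,
    )
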