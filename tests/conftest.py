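import numpy as np
import pytest
from hypothesis import settings

from rampasym import stimuli, synth

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

RATE = 31.5


@pytest.fixture(scope="session")
def rate():
    return RATE


@pytest.fixture(scope="session")
def wn_specs():
    return stimuli.build_stimulus_set(stimuli.Quality.WHITE_NOISE)


@pytest.fixture(scope="session")
def wn_envs(wn_specs):
    return stimuli.render_battery(wn_specs, RATE)


@pytest.fixture(scope="session")
def ramp_envs(wn_specs):
    """Ramps rendered with generous padding for full-support integrals."""
    ramps = [s for s in wn_specs if s.kind != stimuli.RampKind.CONSTANT]
    return [stimuli.render_envelope(s, RATE, pre_pad=0.5, post_pad=3.0)
            for s in ramps]


@pytest.fixture(scope="session")
def small_dataset():
    """A small full synthetic session shared by pipeline tests."""
    return synth.generate_dataset(seed=7, n_neurons=120, n_trials=10)


@pytest.fixture(scope="session")
def archetype_targets(wn_envs):
    """Noise-free multilayer responses of the six responsive archetypes."""
    model = synth.archetype_model(rate=RATE)
    return np.stack([model.predict(e) for e in wn_envs], axis=1)[:6]
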