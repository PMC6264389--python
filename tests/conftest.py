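import numpy as np
import pytest

from nemasleep import synthetic


@pytest.fixture(scope="session")
def l1_track():
    """A seeded arrested-L1 track with its ground truth (3-h movie)."""
    spec = synthetic.regime_spec("arrested_l1", rng_seed=11)
    track, truth = synthetic.simulate_track(spec)
    return spec, track, truth


@pytest.fixture(scope="session")
def short_stack():
    """A short noisy image stack with one programmed bout at t=400..800 s."""
    spec = synthetic.SimSpec(duration=1200.0, dt=2.0, wake_speed_mean=2.0,
                             speed_noise_sd=0.2, bout_rate=0.0,
                             calcium_amplitude=1.2, calcium_decay_tau=60.0,
                             background_noise_sd=2.0, rng_seed=3)
    track, truth = synthetic.simulate_track(spec, bouts=[(400.0, 800.0)])
    frames = synthetic.simulate_stack(track, spec)
    return spec, track, truth, frames


@pytest.fixture
def rng():
    return np.random.default_rng(0)
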