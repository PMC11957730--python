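import numpy as np
import pytest

from erpmvpa.simulate import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Desk-scale cohort for fast structural tests: 4 participants, short epochs."""
    return GeneratorConfig(
        n_participants=4,
        n_trials_per_condition=10,
        srate=125.0,
        epoch_window=(-200.0, 600.0),
        effects={},
        seed=7,
    )


@pytest.fixture
def quiet_cfg():
    """Noise-free cohort (deterministic waveforms only)."""
    return GeneratorConfig(
        n_participants=2,
        n_trials_per_condition=6,
        srate=125.0,
        epoch_window=(-200.0, 600.0),
        latency_jitter_sd=0.0,
        amplitude_jitter_sd=0.0,
        pink_noise_sd=0.0,
        white_noise_sd=0.0,
        effects={},
        seed=3,
    )
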