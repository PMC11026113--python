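import pytest

from dodsfx import synthetic as syn


@pytest.fixture
def train_cfg():
    return syn.TrainConfig()


@pytest.fixture
def always_hit():
    """Hit model with probability 1 everywhere: every pulse yields a frame."""
    return syn.HitModel(base_rate=1.0, within_droplet_decay=1.0, droplet_decay=1.0)


@pytest.fixture
def quiet_sample():
    """Noise-free sample: observed cells are exact images of the scaling model."""
    return syn.SampleModel(cell_noise_rel=0.0)


@pytest.fixture
def flat_chirp():
    """No drift, no jitter: every pulse at 9290 eV."""
    return syn.ChirpModel(e_start=9290.0, e_slope=0.0, e_jitter_sd=0.0)
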