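import numpy as np
import pytest

import attentrain as at


@pytest.fixture(scope="session")
def separated_calibration():
    """Well-separated calibration run: theta/beta amplitude ratio 4 vs 0.5."""
    return at.simulate_calibration(
        attentive=at.ATTENTIVE_PROFILE,
        inattentive=at.INATTENTIVE_PROFILE,
        n_epochs_per_label=20, epoch_len=10.0, fs=128.0, seed=3)


@pytest.fixture(scope="session")
def fitted_model(separated_calibration):
    return at.fit_attention_model(separated_calibration)


@pytest.fixture(scope="session")
def quiet_profile():
    """Low-amplitude artifact-free profile (no blinks, well below the rail)."""
    return at.StateProfile(theta_amp=4.0, alpha_amp=6.0, beta_amp=4.0,
                           pink_noise_amp=10.0, blink_rate=0.0, blink_amp=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
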