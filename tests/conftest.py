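import numpy as np
import pytest

import blinkfuse as bf


@pytest.fixture(scope="session")
def small_epochs():
    """Noise-free three-condition epochs with default lags (160/200/240 ms)."""
    cfg = bf.SimConfig(snr=np.inf, seed=11)
    epochs, truth = bf.simulate_epochset(cfg, n_epochs_per_condition=10)
    return epochs, truth


@pytest.fixture(scope="session")
def noisy_epochs():
    """Moderately noisy epochs (snr 5) for statistical-property tests."""
    cfg = bf.SimConfig(snr=5.0, seed=23)
    epochs, truth = bf.simulate_epochset(cfg, n_epochs_per_condition=40)
    return epochs, truth
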