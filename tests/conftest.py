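import numpy as np
import pytest

from neurostate import synthetic as syn


@pytest.fixture(scope="session")
def canonical32():
    maps, pos = syn.make_canonical_templates(32)
    return maps, pos


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort: study-condition noise levels, reduced sizes."""
    return syn.simulate_cohort(
        seed=7,
        eeg_params=syn.EEGSimParams(duration_s=30, n_channels=16),
        bold_params=syn.BOLDSimParams(),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
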