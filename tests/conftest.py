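import numpy as np
import pytest

from ssvepkit import (
    GeneratorConfig,
    NLCCAHyper,
    StimulusGrid,
    bandpass_zero_phase,
    generate_dataset,
    train_stimulus_models,
)

#: Samples trimmed from stimulus onset to skip the transient stage (~200 ms).
TRANSIENT_TRIM = 50
#: One-second analysis window at the 256 Hz recording rate.
WINDOW = 256


@pytest.fixture(scope="session")
def grid():
    return StimulusGrid.default()


@pytest.fixture(scope="session")
def high_snr_split():
    """Filtered high-SNR session split into 24 training / 60 held-out trials.

    Phase is locked to stimulus onset (the structure template methods
    rely on); trials are pre-trimmed past the transient stage so sample 0
    is steady state.
    """
    cfg = GeneratorConfig(snr_db=10.0, phase_mode="fixed", n_blocks=7, seed=7)
    epochs = bandpass_zero_phase(generate_dataset(cfg))
    epochs = epochs.with_data(
        epochs.data[:, :, TRANSIENT_TRIM:], onset_offset=TRANSIENT_TRIM
    )
    return epochs.split_blocks([2, 3, 4, 5, 6])


@pytest.fixture(scope="session")
def nlcca_models(high_snr_split):
    train, _ = high_snr_split
    return train_stimulus_models(
        train, WINDOW, hyper=NLCCAHyper(restarts=2, max_iter=200, seed=0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
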