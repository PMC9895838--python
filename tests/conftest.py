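import numpy as np
import pytest

from trfsize.containers import NoiseSpec
from trfsize.synth import (assemble_trialset, default_kernel_specs,
                           generate_dataset, make_ground_truth_trf,
                           simulate_eeg, simulate_stimulus)


@pytest.fixture(scope="session")
def small_noiseless_trialset():
    """Small noiseless dataset: 2 features, 4 channels, repeated-test."""
    trials, trf = generate_dataset(
        n_trials=30, channel_count=4, feature_config=("envelope", "pitch"),
        snr_db=np.inf,
        design={"repeated-test": {"n_test_stimuli": 4, "n_repeats": 3}},
        seed=101)
    return trials, trf


@pytest.fixture(scope="session")
def small_noisy_trialset():
    """Same structure with pink noise at 0 dB."""
    trials, trf = generate_dataset(
        n_trials=30, channel_count=4, feature_config=("envelope", "pitch"),
        snr_db=0.0,
        design={"repeated-test": {"n_test_stimuli": 4, "n_repeats": 3}},
        seed=202)
    return trials, trf


@pytest.fixture()
def tiny_trf():
    names = ["envelope", "pitch"]
    spec = {
        "envelope": {"latency": 0.1, "width": 0.03, "amplitude": 1.0},
        "pitch": {"latency": 0.15, "width": 0.04, "amplitude": -0.5},
    }
    return make_ground_truth_trf(names, 3, 128.0, spec, seed=7)
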