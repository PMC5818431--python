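"""Shared fixtures: the packaged subject table and small synthetic subjects.

Synthetic recordings use 16 channels at 128 Hz — the generator is
rate-agnostic and this keeps the exhaustive 120-separation cross-validation
fast enough to run many seeds.
"""

import numpy as np
import pytest

from mipredict import (GeneratorConfig, bandpass, epoch, generate_subject,
                       load_subject_table)
from mipredict.preprocess import EpochSet

TEST_CHANNELS = 16
TEST_RATE = 128.0


@pytest.fixture(scope="session")
def table2():
    return load_subject_table("table2")


def make_subject_epochs(erd_depth, seed, snr=0.4, n_runs=5,
                        trials_per_class_per_run=20):
    """Generate, band-pass (8–30 Hz) and epoch one synthetic subject."""
    cfg = GeneratorConfig(n_channels=TEST_CHANNELS, sampling_rate=TEST_RATE,
                          erd_depth=erd_depth, snr=snr, n_runs=n_runs,
                          trials_per_class_per_run=trials_per_class_per_run,
                          seed=seed)
    return epoch(bandpass(generate_subject(cfg)))


@pytest.fixture(scope="session")
def strong_subject_epochs():
    """High-SNR, deep-ERD subject: should decode far above chance."""
    return make_subject_epochs(erd_depth=0.8, snr=1.5, seed=11)


@pytest.fixture(scope="session")
def null_subject_epochs():
    """No ERD: classes statistically identical, decoding at chance."""
    return make_subject_epochs(erd_depth=0.0, seed=12)


def make_noise_epochs(n_trials=40, n_channels=4, n_samples=64, seed=0,
                      n_runs=1):
    """White-noise EpochSet with balanced labels, for unit-level tests."""
    rng = np.random.default_rng(seed)
    labels = np.array(["left", "right"] * (n_trials // 2))
    runs = np.repeat(np.arange(n_runs), n_trials // n_runs)
    return EpochSet(epochs=rng.standard_normal((n_trials, n_channels,
                                                n_samples)),
                    labels=labels, run_index=runs, sampling_rate=TEST_RATE)
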