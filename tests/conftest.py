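"""Shared fixtures: reduced-rate paradigm and small synthetic datasets.

Simulations run at reduced sampling rates (EEG 250 or 64 Hz, sEMG in the
same 2:3 ratio) so the suite stays fast; rate-dependent arithmetic is always
checked against the full-rate paradigm separately.
"""

import numpy as np
import pytest

from dcafusion.paradigm import make_paradigm_timeline
from dcafusion.preprocess import preprocess_dataset
from dcafusion.simulate import make_dataset, simulate_subject_profile


@pytest.fixture(scope="session")
def spec_full():
    return make_paradigm_timeline()


@pytest.fixture(scope="session")
def spec_mid():
    """250 Hz EEG / 375 Hz sEMG: fast but spectrally faithful (mu, beta and
    a wide sEMG band all fit below Nyquist)."""
    return make_paradigm_timeline(fs_eeg=250.0, fs_emg=375.0)


@pytest.fixture(scope="session")
def spec_tiny():
    """64 Hz EEG / 96 Hz sEMG: for training experiments."""
    return make_paradigm_timeline(fs_eeg=64.0, fs_emg=96.0)


@pytest.fixture(scope="session")
def profile():
    return simulate_subject_profile(1, seed=42)


@pytest.fixture(scope="session")
def small_dataset(spec_mid):
    """2 subjects x 1 group x 4 trials/class = 24 continuous trials."""
    return make_dataset(n_subjects=2, groups=1, trials_per_class_per_group=4,
                        seed=7, spec=spec_mid)


@pytest.fixture(scope="session")
def small_trials(small_dataset, spec_mid):
    return preprocess_dataset(small_dataset, spec_mid, side="left")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
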