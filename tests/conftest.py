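import numpy as np
import pytest

from lexosc.config import AnalysisConfig, SyntheticConfig
from lexosc.montage import load_montage


@pytest.fixture(scope="session")
def montage():
    return load_montage("study38")


@pytest.fixture()
def analysis_config():
    return AnalysisConfig()


@pytest.fixture()
def tiny_synth():
    """Small cohort configuration for fast structural tests."""
    return SyntheticConfig(n_subjects=2, trials_per_condition=8, rng_seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_epochs(data, sfreq=500.0, tmin=-1.0, channels=None, task=None,
                cognate=None, correct=None, subject_id="S00"):
    """Convenience constructor for EpochedDataset test fixtures."""
    from lexosc.containers import EpochedDataset

    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    return EpochedDataset(
        data=data, sfreq=sfreq,
        times=tmin + np.arange(n_samp) / sfreq,
        channels=channels or [f"ch{i}" for i in range(n_ch)],
        task=np.array(task if task is not None else ["naming"] * n_trials),
        cognate=np.array(cognate if cognate is not None
                         else ["noncognate"] * n_trials),
        correct=np.array(correct if correct is not None
                         else [True] * n_trials, dtype=bool),
        subject_id=subject_id)
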