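import numpy as np
import pytest

import wmentropy as wm


@pytest.fixture(scope="session")
def cohort16():
    """One 16-channel default-size cohort shared across tests."""
    cfg = wm.SynthConfig(n_channels=16, seed=11)
    epochs, behavior, truth = wm.generate_cohort(cfg)
    return cfg, epochs, behavior, truth


@pytest.fixture(scope="session")
def features16(cohort16):
    """Retention-period entropy features of the shared cohort."""
    _, epochs, _, _ = cohort16
    retention = [wm.extract_retention(e) for e in epochs]
    return wm.cohort_entropy(retention)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiny_epochs(data, fs=250.0, channels=None, t0=0.0, **kw):
    """Helper: wrap a raw array as an EpochArray with minimal metadata."""
    data = np.asarray(data, dtype=float)
    if channels is None:
        channels = [f"ch{i}" for i in range(data.shape[1])]
    return wm.EpochArray(
        subject=1, session=1, data=data, fs=fs, channels=channels, t0=t0, **kw
    )
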