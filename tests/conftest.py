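import numpy as np
import pytest

from tvdfc.ingest import BAND_BY_NAME, Epoch
from tvdfc.synthdata import SimConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220819)


@pytest.fixture
def tiny_sim():
    """Desk-scale generator config used by several module tests."""
    return SimConfig(
        n_subjects=2, n_channels=6, n_events_per_subject=4, seed=7
    )


def make_epoch(data, sfreq=250.0, band="alpha", subject="sub-01"):
    """Wrap a channels x 1750 array as a band epoch."""
    return Epoch(
        subject=subject,
        data=np.asarray(data, dtype=float),
        sfreq=sfreq,
        channels=[f"ch{i}" for i in range(np.asarray(data).shape[0])],
        band=BAND_BY_NAME[band],
    )
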