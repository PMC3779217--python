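import numpy as np
import pytest

from oddball_consistency.config import ParadigmConfig
from oddball_consistency.simulate import EpochSet


@pytest.fixture(scope="session")
def paradigm():
    return ParadigmConfig()


@pytest.fixture
def make_epochs():
    """Factory for small hand-built epoch sets."""

    def _make(data, fs_hz=250.0, t0_ms=-600.0, labels=None, channels=None):
        data = np.asarray(data, dtype=float)
        n_tr, n_ch, _ = data.shape
        labels = tuple(labels) if labels is not None else ("standard",) * n_tr
        channels = (tuple(channels) if channels is not None
                    else tuple(f"ch{i}" for i in range(n_ch)))
        return EpochSet(data=data, fs_hz=fs_hz, t0_offset_ms=t0_ms,
                        channel_names=channels, labels=labels)

    return _make


@pytest.fixture(scope="session")
def clean_subject(paradigm):
    """One default-condition synthetic subject (cached per session)."""
    from oddball_consistency.simulate import default_effects, simulate_subject

    profile, epochs = simulate_subject(paradigm, default_effects(), 7, 0)
    return profile, epochs
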