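import numpy as np
import pytest

from microcoh import SimSpec, build_scales, insilico_pair
from microcoh.io_preproc import EpochArray


@pytest.fixture(scope="session")
def small_spec():
    """Compact scale grid for fast tests: fs=250, 2 s, 6 octaves (73 scales)."""
    return build_scales(250.0, 2.0, n_octaves=6)


@pytest.fixture(scope="session")
def insilico_epochs():
    """The default piecewise cosine/sine pair, 30 trials, seed 1."""
    return insilico_pair(SimSpec(seed=1))


@pytest.fixture(scope="session")
def insilico_map(insilico_epochs):
    from microcoh.coherency import ensemble_wtc
    from microcoh.wavelet_engine import build_scales as bs

    spec = bs(insilico_epochs.fs, insilico_epochs.n_samples / insilico_epochs.fs)
    return ensemble_wtc(insilico_epochs, "x", "y", spec)


def white_noise_epochs(n_epochs, n_channels, n_samples, fs, seed, sd=1.0):
    rng = np.random.default_rng(seed)
    data = sd * rng.standard_normal((n_epochs, n_channels, n_samples))
    labels = [f"c{i}" for i in range(n_channels)]
    return EpochArray(data=data, fs=fs, t0_index=0, channel_labels=labels)
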