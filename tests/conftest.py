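import numpy as np
import pytest

from ampmod import SynthSpec, gen_pac_trial
from ampmod.recordings_io import DEAP_EEG_CHANNELS, Recording

FS = 128.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_spec():
    """Short two-channel trial spec for fast DSP-level tests."""
    return SynthSpec(seed=11, channels=("F3", "F4"), stimulus_s=20.0)


@pytest.fixture(scope="session")
def full_montage_recording():
    """One 32-EEG-channel + GSR trial with the full protocol durations.

    Session-scoped: several count-oriented tests share it.
    """
    spec = SynthSpec(seed=5, channels=tuple(DEAP_EEG_CHANNELS),
                     am_depth=0.5, pac_depth=0.4)
    return gen_pac_trial(spec)


def make_recording(data, fs=FS, baseline_s=3.0, channels=None, **kw):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if channels is None:
        channels = [f"ch{i}" for i in range(data.shape[0])]
    nb = int(baseline_s * fs)
    return Recording(list(channels), data, fs, (0, nb), (nb, data.shape[1]),
                     **kw)
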