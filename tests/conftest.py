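import numpy as np
import pytest

import snnmorph as sm
from snnmorph.encoding import EncoderParams


@pytest.fixture(scope="session")
def montage():
    return sm.make_default_montage()


@pytest.fixture(scope="session")
def small_grid():
    """Tiny deterministic grid for fast reservoir tests."""
    return sm.synthetic_grid(4)


@pytest.fixture(scope="session")
def analysis_grid():
    """The ~500-neuron desk-scale grid."""
    return sm.synthetic_grid(11)


@pytest.fixture(scope="session")
def short_fixture(montage):
    """10 s six-condition study fixture (seed 1)."""
    return sm.make_study_fixture(1, montage, duration=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def encoder():
    return EncoderParams(sf_threshold=0.1)


def toy_recording(data, rate=256.0, labels=None, condition=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return sm.EEGRecording(data, rate, labels, condition)
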