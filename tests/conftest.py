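import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from leashwalk.ethogram import default_catalog
from leashwalk.signal_prep import UniformTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_uniform(force, dir=None, rate=10.0, tarred=True, smoothed=0):
    """Helper: wrap a force array as a UniformTrace for detection tests."""
    force = np.asarray(force, dtype=float)
    if dir is None:
        dir = np.zeros_like(force)
    return UniformTrace(t0=0.0, rate=rate, force=force, dir=np.asarray(dir, float),
                        tarred=tarred, smoothed=smoothed)
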