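import numpy as np
import pytest

from polyprint.minutiae import BIFURCATION, TERMINATION, Minutia, MinutiaSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_set(coords, types=None, extent=300):
    """Build a MinutiaSet from (x, y) pairs, alternating types by default."""
    if types is None:
        types = [TERMINATION if i % 2 == 0 else BIFURCATION for i in range(len(coords))]
    ms = [Minutia(float(x), float(y), t) for (x, y), t in zip(coords, types)]
    return MinutiaSet(ms, width=extent, height=extent, provenance="raw")


@pytest.fixture
def make_minutia_set():
    return make_set
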