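import numpy as np
import pytest

from reachrisk import GainFunction


@pytest.fixture
def gf():
    return GainFunction()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def piecewise_gain(e, boundary=30.0, max_score=100.0, dead_zone=7.0):
    """Independent direct evaluation of the linear-ramp score."""
    if e > boundary or e <= dead_zone:
        return 0.0
    return max_score * (e - dead_zone) / (boundary - dead_zone)
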