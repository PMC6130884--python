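import numpy as np
import pytest

from gdhl.signals import EventSpec, TimeGrid, cosine_event


@pytest.fixture
def grid():
    return TimeGrid(-2.0, 0.001, 4001)


@pytest.fixture
def event():
    return EventSpec(center=0.0, half_width=0.5, amplitude=1.0)


@pytest.fixture
def event_signal(grid, event):
    return cosine_event(event, grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
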