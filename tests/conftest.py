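import numpy as np
import pytest

from farrowwatch import (
    BoundingBox,
    DetectionEvent,
    PostureLabel,
    PostureTimeline,
)

LL = PostureLabel.LATERAL_LYING
ST = PostureLabel.STERNAL_LYING
SD = PostureLabel.STANDING
SI = PostureLabel.SITTING


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_event(t, label="standing", conf=0.9, box=(0, 0, 10, 10)):
    return DetectionEvent(t=t, label=str(label), box=BoundingBox(*box), conf=conf)


def random_timeline(rng, n=None, dt=60.0, p_missing=0.2):
    """Regular timeline with random labels and random missing samples."""
    if n is None:
        n = int(rng.integers(80, 400))
    codes = rng.integers(0, 4, n).astype(np.int8)
    codes[rng.random(n) < p_missing] = -1
    return PostureTimeline(times=np.arange(n) * dt, codes=codes)


@pytest.fixture
def make_random_timeline(rng):
    return lambda **kw: random_timeline(rng, **kw)
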