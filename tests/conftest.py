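import numpy as np
import pytest
from hypothesis import settings

from lcrtrack import ImageStack, RunConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return RunConfig()


@pytest.fixture
def small_stack(rng):
    """A 10-frame 16x32 stack: dark background plus a bright band."""
    frames = np.full((10, 16, 32), 10.0)
    frames[:, 5:11, 4:28] = 100.0
    frames += rng.normal(0, 1.0, frames.shape)
    frames = np.clip(frames, 0, None)
    return ImageStack(frames, pixel_size_um=0.25, frame_interval_ms=10.0)


def make_stack(frames, pixel_size_um=0.25, frame_interval_ms=10.0):
    return ImageStack(np.asarray(frames, dtype=float), pixel_size_um, frame_interval_ms)
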