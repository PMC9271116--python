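import numpy as np
import pytest
from hypothesis import settings

from rtcine import physio
from rtcine.phantom import PhantomConfig, simulate_acquisition

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


SMALL_PHANTOM = dict(
    matrix=128,
    pixel_mm=2.5,
    n_slices=8,
    duration_s=20.0,
)

TINY_PHANTOM = dict(
    matrix=32,
    pixel_mm=8.0,
    n_slices=2,
    duration_s=8.0,
    lv_edv_ml=20.0,
    lv_esv_ml=8.0,
    rv_edv_ml=16.0,
    rv_esv_ml=7.0,
)


def make_phantom(seed=0, tiny=False, **overrides):
    base = dict(TINY_PHANTOM if tiny else SMALL_PHANTOM)
    base.update(overrides)
    return PhantomConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def small_run():
    """One reduced phantom acquisition with bellows already assigned."""
    cfg = make_phantom(seed=3)
    series, trace, truth = simulate_acquisition(cfg)
    prepared = physio.preprocess_trace(trace)
    physio.assign_bellows_to_frames(prepared, series)
    return cfg, series, trace, truth


@pytest.fixture(scope="session")
def tiny_run():
    """A very small acquisition for I/O round trips."""
    cfg = make_phantom(seed=1, tiny=True)
    series, trace, truth = simulate_acquisition(cfg)
    return cfg, series, trace, truth


def make_frame(bellows=None, trigger=0.0, acq=0.0, value=0, shape=(4, 4)):
    from rtcine.core import RTFrame

    return RTFrame(
        pixels=np.full(shape, value, dtype=np.uint16),
        acq_time=acq,
        trigger_time=trigger,
        bellows=bellows,
    )
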