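import numpy as np
import pytest

from pulsebold import BoldSeries, PulseTrace, TissueMasks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_masks():
    """An 8x8x2 grid with disjoint GM / WM blocks and free corners."""
    gm = np.zeros((8, 8, 2), dtype=bool)
    wm = np.zeros((8, 8, 2), dtype=bool)
    gm[2:4, 2:6, :] = True
    wm[4:6, 2:6, :] = True
    return TissueMasks({"GM": gm, "WM": wm})


@pytest.fixture
def flat_series(rng):
    """Constant 100 everywhere plus tiny noise; 8x8x2x64 at TR 0.25 s."""
    data = 100.0 + rng.normal(0, 0.01, size=(8, 8, 2, 64))
    return BoldSeries(data=data, tr_seconds=0.25)


@pytest.fixture
def constant_pulse():
    times = np.arange(0.0, 120.0, 1.0)
    return PulseTrace(times_seconds=times, bpm=np.full(times.size, 60.0))


def make_series(courses_by_region, shape=(8, 8, 2), n=500, tr=0.25, fill=0.0):
    """Build a BoldSeries from {mask: 1D course} pairs on a small grid."""
    data = np.full(shape + (n,), fill, dtype=float)
    for mask, course in courses_by_region:
        data[mask] = course
    return BoldSeries(data=data, tr_seconds=tr)
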