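import numpy as np
import pytest
from hypothesis import settings

from eerkit import DetectorGeometry, EventMovie

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def geometry16():
    return DetectorGeometry(16, 16, u=4, frame_rate=240.0)


@pytest.fixture
def geometry64():
    return DetectorGeometry(64, 64, u=4, frame_rate=100.0)


def random_frame_events(rng, geometry, p):
    """One Bernoulli frame: distinct hit pixels in scanline order."""
    n_pix = geometry.n_pixels
    hits = np.nonzero(rng.random(n_pix) < p)[0]
    px = hits % geometry.width
    py = hits // geometry.width
    sx = rng.integers(0, geometry.u, size=hits.size)
    sy = rng.integers(0, geometry.u, size=hits.size)
    return px, py, sx, sy


def random_movie(rng, geometry, p, n_frames, metadata=None):
    cols = [[], [], [], [], []]
    for f in range(n_frames):
        px, py, sx, sy = random_frame_events(rng, geometry, p)
        cols[0].append(np.full(px.size, f))
        for c, a in zip(cols[1:], (px, py, sx, sy)):
            c.append(a)
    arrays = [np.concatenate(c) if c else np.zeros(0, int) for c in cols]
    return EventMovie(geometry, n_frames, *arrays, metadata)
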