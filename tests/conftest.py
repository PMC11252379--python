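import numpy as np
import pytest

from meiotrack import Track, TrackSet


@pytest.fixture
def straight_track():
    """5 frames along +x at 0.1 µm per 2 s step."""
    t = np.arange(5) * 2.0
    xyz = np.c_[np.arange(5) * 0.1, np.zeros(5), np.zeros(5)]
    return Track("straight", t, xyz, anther_id="a0", cell_id="c0", frames=np.arange(5))


@pytest.fixture
def two_track_set(straight_track):
    t = np.arange(5) * 2.0
    somatic = Track(
        "soma",
        t,
        np.c_[np.full(5, 3.0), np.arange(5) * 0.01, np.zeros(5)],
        anther_id="a0",
        cell_id="s0",
        compartment="somatic",
        frames=np.arange(5),
    )
    return TrackSet([straight_track, somatic], frame_interval=2.0)


def make_track(xyz, dt=1.0, track_id="t", **kw):
    xyz = np.asarray(xyz, dtype=float)
    t = np.arange(len(xyz)) * dt
    return Track(track_id, t, xyz, frames=np.arange(len(xyz)), **kw)
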