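import numpy as np
import pytest

from stopgo.datatypes import Track, TrackSet


def track_from_speeds(speeds_um_min, dt_s=10.0, cell_id="c0", dim=2):
    """Build a straight-line track whose step speeds are exactly as given."""
    speeds = np.asarray(speeds_um_min, dtype=float)
    n = len(speeds) + 1
    pos = np.zeros((n, dim))
    pos[1:, 0] = np.cumsum(speeds / 60.0 * dt_s)
    return Track(cell_id=cell_id, t_s=np.arange(n) * dt_s, pos_um=pos)


def track_from_positions(positions, dt_s=10.0, cell_id="c0"):
    pos = np.asarray(positions, dtype=float)
    return Track(cell_id=cell_id, t_s=np.arange(len(pos)) * dt_s, pos_um=pos)


@pytest.fixture
def straight_track():
    """Ballistic 2D track at 6 µm/min (1 µm per 10 s step)."""
    return track_from_speeds([6.0] * 20, dt_s=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_trackset(rng):
    tracks = []
    for i in range(5):
        pos = np.cumsum(rng.normal(0, 1.0, size=(20, 2)), axis=0)
        tracks.append(
            Track(cell_id=f"c{i}", t_s=np.arange(20) * 10.0, pos_um=pos)
        )
    return TrackSet(tracks=tracks, group="test")
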