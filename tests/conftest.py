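import numpy as np
import pytest

from usvmap import CallEvent, Trajectory, default_geometry


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


def make_track(t, x, y, session_id="test", strain=""):
    return Trajectory(
        session_id=session_id,
        subject_id=session_id,
        strain_label=strain,
        t=np.asarray(t, dtype=float),
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
    )


def make_call(t_start, duration, freq, call_id="c"):
    return CallEvent(call_id, t_start, t_start + duration, duration, freq)


@pytest.fixture
def line_track():
    """Two-sample track from (0,0) to (10,0) over 1 s."""
    return make_track([0.0, 1.0], [0.0, 10.0], [0.0, 0.0])


def random_track(rng, n=100, rate=25.0, box=60.0, session_id="rand"):
    t = np.arange(n) / rate
    x = np.clip(np.cumsum(rng.normal(0, 0.6, n)) + box / 2, 0, box)
    y = np.clip(np.cumsum(rng.normal(0, 0.6, n)) + box / 2, 0, box)
    return make_track(t, x, y, session_id=session_id)
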