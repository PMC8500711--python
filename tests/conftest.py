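import numpy as np
import pytest

from riskforage.session import EventLog, Session, SpikeTrain, Tracking


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def linear_tracking(duration=10.0, speed=30.0, rate=30.0, x0=0.0, y=0.0):
    """Straight-line run along x at constant speed."""
    t = np.arange(int(duration * rate)) / rate
    return Tracking(t=t, x=x0 + speed * t, y=np.full(t.size, y))


@pytest.fixture
def simple_session():
    """Two-trial session with one cell per region and a clean event log."""
    t = np.arange(0, 60 * 30) / 30.0
    x = 20.0 * np.sin(2 * np.pi * t / 60.0) + 20.0
    tracking = Tracking(t=t, x=x, y=np.zeros_like(t))
    events = EventLog.from_records(
        [
            (1, "gate_open", 1.0),
            (1, "pellet_procured", 6.0),
            (1, "trial_end", 12.0),
            (2, "gate_open", 20.0),
            (2, "pellet_procured", 27.5),
            (2, "trial_end", 35.0),
        ]
    )
    trains = (
        SpikeTrain("ba1", "BA", np.round(np.arange(0.5, 59.0, 0.37), 4), spike_width=0.4),
        SpikeTrain("hpc1", "dHPC", np.round(np.arange(0.2, 59.0, 0.73), 4)),
    )
    return Session(
        session_id="fix01",
        phase="pre_threat",
        tracking=tracking,
        events=events,
        trains=trains,
        duration=float(t[-1]),
    )
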