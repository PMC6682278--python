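import numpy as np
import pandas as pd
import pytest

from clickchain import (
    Dialect,
    LogEvent,
    RawLog,
    StateSpace,
    TransitionModel,
    start2cycle_reference_model,
)


@pytest.fixture(scope="session")
def reference_model() -> TransitionModel:
    """Packaged Start2Cycle chain (printed 2-decimal matrix, 9 pages + exit)."""
    return start2cycle_reference_model()


@pytest.fixture(scope="session")
def abc_states() -> StateSpace:
    return StateSpace(pages=("A", "B", "C"))


@pytest.fixture(scope="session")
def abc_chain(abc_states) -> TransitionModel:
    """Small fully-specified 3-page chain used as a likelihood oracle target."""
    P = np.array(
        [
            [0.1, 0.4, 0.2, 0.3],  # A
            [0.3, 0.1, 0.4, 0.2],  # B
            [0.25, 0.25, 0.1, 0.4],  # C
            [0.0, 0.0, 0.0, 0.0],  # Exit
        ]
    )
    pi = np.array([0.5, 0.3, 0.2, 0.0])
    return TransitionModel(states=abc_states, P=P, pi=pi)


def make_events(rows):
    """rows: (user, minutes-offset, page) triples -> RawLog."""
    t0 = pd.Timestamp("2017-09-01T08:00:00Z")
    return RawLog(
        events=[
            LogEvent(user_id=u, timestamp=t0 + pd.Timedelta(minutes=m), page=p)
            for u, m, p in rows
        ],
        dialect=Dialect.EVENT,
    )


@pytest.fixture
def simple_log() -> RawLog:
    return make_events(
        [
            ("u1", 0, "A"),
            ("u1", 10, "B"),
            ("u1", 50, "C"),  # 40-min gap: new session
            ("u2", 5, "A"),
            ("u2", 5, "A"),  # repeat to collapse
            ("u2", 20, "B"),
        ]
    )
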