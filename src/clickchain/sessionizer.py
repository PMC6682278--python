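"""Inactivity-gap sessionization of per-user event streams.

No session identifier is logged by the app, so sessions are reconstructed
heuristically: a user's consecutive actions belong to the same session as
long as no more than ``gap_threshold`` (default 30 minutes) of inactivity
separates them.  A gap of exactly the threshold stays in-session; a
strictly larger gap opens a new one.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .log_io import RawLog

__all__ = ["Session", "sessionize", "filter_sessions", "DEFAULT_GAP"]

DEFAULT_GAP = pd.Timedelta(minutes=30)


@dataclasses.dataclass
class Session:
    """One user's ordered trail of page states within a single visit.

    ``trail`` never includes the exit state; ``n_events`` is the raw event
    count before repeat-collapsing, so event conservation can be checked
    whatever the collapsing flag.
    """

    user_id: str
    trail: list[str]
    start: pd.Timestamp
    end: pd.Timestamp
    session_index: int
    n_events: int

    def __post_init__(self) -> None:
        if not self.trail:
            raise ValueError("session trail must be non-empty")
        if self.start > self.end:
            raise ValueError("session start is after its end")

    def __len__(self) -> int:
        return len(self.trail)


def _collapse(pages: list[str]) -> list[str]:
    out = [pages[0]]
    for p in pages[1:]:
        if p != out[-1]:
            out.append(p)
    return out


def sessionize(
    log: RawLog,
    gap_threshold: pd.Timedelta = DEFAULT_GAP,
    collapse_repeats: bool = True,
) -> list[Session]:
    """Segment a raw log into sessions by the inactivity-gap heuristic.

    Parameters
    ----------
    log
        Per-user time-sorted events (as produced by :func:`~clickchain.log_io.read_log`).
    gap_threshold
        Maximum in-session inactivity; a strictly larger gap splits.
    collapse_repeats
        Merge consecutive identical pages within a session into one state
        occurrence (page refreshes do not count as self-transitions).

    Returns
    -------
    list of :class:`Session`, ordered by user then time, with a per-user
    ``session_index`` starting at 0.  Before collapsing, every event
    belongs to exactly one session.
    """
    gap_threshold = pd.Timedelta(gap_threshold)
    if gap_threshold < pd.Timedelta(0):
        raise ValueError("gap_threshold must be non-negative")

    sessions: list[Session] = []
    per_user: dict[str, list] = {}
    for ev in log.events:
        per_user.setdefault(ev.user_id, []).append(ev)

    for user_id, events in per_user.items():
        index = 0
        block = [events[0]]
        for prev, ev in zip(events, events[1:]):
            if ev.timestamp - prev.timestamp > gap_threshold:
                sessions.append(_make_session(user_id, block, index, collapse_repeats))
                index += 1
                block = [ev]
            else:
                block.append(ev)
        sessions.append(_make_session(user_id, block, index, collapse_repeats))
    return sessions


def _make_session(user_id, events, index, collapse_repeats) -> Session:
    pages = [ev.page for ev in events]
    return Session(
        user_id=user_id,
        trail=_collapse(pages) if collapse_repeats else pages,
        start=events[0].timestamp,
        end=events[-1].timestamp,
        session_index=index,
        n_events=len(events),
    )


def filter_sessions(
    sessions: list[Session], min_len: int = 2, max_len: int = 20
) -> list[Session]:
    """Keep sessions whose trail length lies in ``[min_len, max_len]``.

    Length is counted on the (possibly collapsed) trail, exit excluded;
    both bounds are inclusive and order is preserved.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    return [s for s in sessions if min_len <= len(s.trail) <= max_len]
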