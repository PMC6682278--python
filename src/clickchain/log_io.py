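"""Reading and writing raw app logs, matrices and event streams.

Two log dialects are supported:

* **event stream** — one row per page view: ``user_id, timestamp, page``.
* **click stream** — one row per click: ``user_id, timestamp, source,
  destination``.  Click rows are expanded to page-visit events by emitting
  the destination of every click and prepending the first click's source
  once per user, so a block of *k* clicks yields a trail of *k* + 1 page
  views.  Source/previous-destination mismatches are tolerated by trusting
  destinations.

Timestamps are parsed as ISO-8601 and normalized to UTC (naive stamps are
assumed UTC) so that inactivity-gap computation is timezone-stable.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import warnings
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "LogEvent",
    "RawLog",
    "StateSpace",
    "SchemaError",
    "TimestampError",
    "read_log",
    "write_events",
    "read_events",
    "write_matrix",
    "read_matrix",
]


class SchemaError(ValueError):
    """A required column is missing from the input."""


class TimestampError(ValueError):
    """A row's timestamp could not be parsed; carries the line number."""


class Dialect(str, enum.Enum):
    EVENT = "event"
    CLICK = "click"


_REQUIRED_COLUMNS = {
    Dialect.EVENT: ("user_id", "timestamp", "page"),
    Dialect.CLICK: ("user_id", "timestamp", "source", "destination"),
}


@dataclasses.dataclass(frozen=True)
class LogEvent:
    """One user action: a page view with its timestamp."""

    user_id: str
    timestamp: pd.Timestamp
    page: str

    def __post_init__(self) -> None:
        if not self.page:
            raise ValueError("page label must be non-empty")


@dataclasses.dataclass(frozen=True)
class StateSpace:
    """Ordered page vocabulary plus the surrogate exit state.

    The exit state models leaving the app: every session's final page view
    is followed by one transition into it, and it is absorbing.  Index *i*
    maps to page *i* for ``i < n_pages`` and the exit state sits last, so
    serialization order is reproducible.
    """

    pages: tuple[str, ...]
    exit_label: str = "Exit"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pages", tuple(self.pages))
        if len(set(self.pages)) != len(self.pages):
            raise ValueError("page labels must be unique")
        if self.exit_label in self.pages:
            raise ValueError(f"exit label {self.exit_label!r} collides with a page")

    @property
    def n_pages(self) -> int:
        return len(self.pages)

    @property
    def n_states(self) -> int:
        """Pages plus the exit state."""
        return len(self.pages) + 1

    @property
    def labels(self) -> tuple[str, ...]:
        """All state labels, exit last."""
        return self.pages + (self.exit_label,)

    @property
    def exit_index(self) -> int:
        return len(self.pages)

    def index(self, label: str) -> int:
        if label == self.exit_label:
            return self.exit_index
        try:
            return self.pages.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label == self.exit_label or label in self.pages

    @classmethod
    def from_events(cls, events: Iterable[LogEvent], exit_label: str = "Exit") -> "StateSpace":
        """State space of the distinct pages in first-appearance order."""
        seen: dict[str, None] = {}
        for ev in events:
            seen.setdefault(ev.page)
        return cls(pages=tuple(seen), exit_label=exit_label)


@dataclasses.dataclass
class RawLog:
    """Time-ordered per-user event stream, sorted by (user_id, timestamp)."""

    events: list[LogEvent]
    dialect: Dialect = Dialect.EVENT

    def __len__(self) -> int:
        return len(self.events)

    def users(self) -> list[str]:
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.user_id)
        return list(seen)

    def events_for(self, user_id: str) -> list[LogEvent]:
        return [ev for ev in self.events if ev.user_id == user_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "user_id": [ev.user_id for ev in self.events],
                "timestamp": [ev.timestamp for ev in self.events],
                "page": [ev.page for ev in self.events],
            }
        )


def _separator_for(source: str | Path | IO[str]) -> str:
    name = getattr(source, "name", source)
    return "\t" if str(name).endswith(".tsv") else ","


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(raw, utc=True, format="ISO8601", errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        line = int(bad.idxmax()) + 2
        raise TimestampError(
            f"unparseable timestamp {raw[bad.idxmax()]!r} at line {line}"
        )
    return parsed


def read_log(source: str | Path | IO[str], dialect: Dialect | str = Dialect.EVENT) -> RawLog:
    """Read a delimited app log into a :class:`RawLog`.

    The delimiter is inferred from the file extension (``.tsv`` → tab,
    otherwise comma).  Events are returned sorted by ``(user_id,
    timestamp)``; click-stream rows are expanded as described in the module
    docstring.  An empty input yields an empty log with a warning.
    """
    dialect = Dialect(dialect)
    df = pd.read_csv(source, sep=_separator_for(source), dtype=str, skipinitialspace=True)
    for col in _REQUIRED_COLUMNS[dialect]:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if df.empty:
        warnings.warn("log input contains no rows", stacklevel=2)
        return RawLog(events=[], dialect=dialect)

    df = df.copy()
    df["timestamp"] = _parse_timestamps(df["timestamp"])
    df = df.sort_values(["user_id", "timestamp"], kind="stable").reset_index(drop=True)

    events: list[LogEvent] = []
    if dialect is Dialect.EVENT:
        for row in df.itertuples(index=False):
            events.append(LogEvent(str(row.user_id), row.timestamp, str(row.page)))
    else:
        for _, block in df.groupby("user_id", sort=False):
            first = block.iloc[0]
            events.append(
                LogEvent(str(first["user_id"]), first["timestamp"], str(first["source"]))
            )
            for row in block.itertuples(index=False):
                events.append(LogEvent(str(row.user_id), row.timestamp, str(row.destination)))
    return RawLog(events=events, dialect=dialect)


def write_events(log: RawLog, dest: str | Path | IO[str]) -> None:
    """Write an event stream as line-delimited JSON (user_id, timestamp, page)."""
    records = (
        json.dumps(
            {"user_id": ev.user_id, "timestamp": ev.timestamp.isoformat(), "page": ev.page}
        )
        for ev in log.events
    )
    text = "\n".join(records) + ("\n" if log.events else "")
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def read_events(source: str | Path | IO[str]) -> RawLog:
    """Read back a line-delimited JSON event stream written by :func:`write_events`."""
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    events = []
    for line in text.splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        events.append(
            LogEvent(rec["user_id"], pd.Timestamp(rec["timestamp"]), rec["page"])
        )
    return RawLog(events=events, dialect=Dialect.EVENT)


def write_matrix(
    matrix: np.ndarray, states: StateSpace, dest: str | Path | IO[str]
) -> None:
    """Write a square matrix over ``states.labels`` as labeled CSV.

    Floats are serialized at full (shortest round-trip) precision so the
    paired :func:`read_matrix` recovers them bit-identically.
    """
    matrix = np.asarray(matrix)
    if matrix.size == 0:
        raise ValueError("matrix is empty")
    n = states.n_states
    if matrix.shape != (n, n):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match state space ({n}, {n})"
        )
    frame = pd.DataFrame(matrix, index=states.labels, columns=states.labels)
    frame.to_csv(dest)


def read_matrix(source: str | Path | IO[str]) -> tuple[np.ndarray, StateSpace]:
    """Read a labeled CSV matrix; the last row/column label is the exit state."""
    frame = pd.read_csv(source, index_col=0)
    labels = [str(c) for c in frame.columns]
    if list(map(str, frame.index)) != labels:
        raise ValueError("matrix row and column labels differ")
    states = StateSpace(pages=tuple(labels[:-1]), exit_label=labels[-1])
    return frame.to_numpy(), states
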