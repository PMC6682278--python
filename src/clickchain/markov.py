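"""First-order Markov-chain estimation, scoring, simulation and summaries.

The chain is defined on the app's page states plus a surrogate *exit*
state: each session trail of *k* pages contributes *k* − 1 internal
transitions and one final transition into exit, so the chain encodes both
navigation and leaving behaviour.  The exit state is absorbing by
convention (its row is all zero and never sampled from).  The initial
distribution π is estimated by counting each session's first page.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .log_io import StateSpace
from .sessionizer import Session

__all__ = [
    "TransitionCounts",
    "TransitionModel",
    "SimulatedTrail",
    "count_transitions",
    "normalize",
    "estimate_initial",
    "fit",
    "sequence_log_likelihood",
    "simulate_session",
    "simulate_trails",
    "page_view_summary",
    "save_model",
    "load_model",
]

_ROW_SUM_ATOL = 1e-9


def _trails(sessions: Sequence[Session] | Sequence[Sequence[str]]) -> list[list[str]]:
    return [list(s.trail) if isinstance(s, Session) else list(s) for s in sessions]


@dataclasses.dataclass
class TransitionCounts:
    """Raw transition counts M over the state space (exit row all zero)."""

    states: StateSpace
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = self.states.n_states
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match state space")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass
class TransitionModel:
    """Row-stochastic transition matrix P with initial distribution π.

    Rows of states with no observed outgoing transition (always including
    exit) are all zero and listed in ``dangling``.
    """

    states: StateSpace
    P: np.ndarray
    pi: np.ndarray
    n_sessions: int | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = self.states.n_states
        if self.P.shape != (n, n):
            raise ValueError("P shape does not match state space")
        if self.pi.shape != (n,):
            raise ValueError("pi length does not match state space")
        if ((self.P < 0) | (self.P > 1)).any():
            raise ValueError("transition probabilities must lie in [0, 1]")

    @property
    def dangling(self) -> list[str]:
        """Non-exit states with an all-zero row (no observed departures)."""
        sums = self.P.sum(axis=1)
        return [
            self.states.labels[i]
            for i in range(self.states.n_pages)
            if sums[i] == 0.0
        ]

    def prob(self, source: str, target: str) -> float:
        return float(self.P[self.states.index(source), self.states.index(target)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.states.labels, columns=self.states.labels)


@dataclasses.dataclass
class SimulatedTrail:
    """A simulated session trail (exit excluded) with a truncation flag."""

    trail: list[str]
    truncated: bool

    def __len__(self) -> int:
        return len(self.trail)


def count_transitions(
    sessions: Sequence[Session] | Sequence[Sequence[str]], states: StateSpace
) -> TransitionCounts:
    """Count transitions over all trails, adding one final → exit per trail.

    A length-1 trail contributes exactly one count (page → exit).  Unknown
    labels raise a :class:`KeyError` naming the label.
    """
    n = states.n_states
    counts = np.zeros((n, n), dtype=np.int64)
    exit_ix = states.exit_index
    for trail in _trails(sessions):
        ix = [states.index(p) for p in trail]
        for a, b in zip(ix, ix[1:]):
            counts[a, b] += 1
        counts[ix[-1], exit_ix] += 1
    return TransitionCounts(states=states, counts=counts)


def normalize(counts: TransitionCounts) -> np.ndarray:
    """Row-normalize counts into probabilities; zero rows stay zero.

    No smoothing is applied — unobserved transitions keep probability 0.
    """
    M = counts.counts.astype(float)
    row_sums = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(row_sums > 0, M / np.where(row_sums == 0, 1.0, row_sums), 0.0)
    return P


def estimate_initial(
    sessions: Sequence[Session] | Sequence[Sequence[str]], states: StateSpace
) -> np.ndarray:
    """π from first visited states: π_i = (#sessions starting at s_i)/#sessions."""
    trails = _trails(sessions)
    if not trails:
        raise ValueError("cannot estimate an initial distribution from zero sessions")
    pi = np.zeros(states.n_states)
    for trail in trails:
        pi[states.index(trail[0])] += 1
    return pi / len(trails)


def fit(
    sessions: Sequence[Session] | Sequence[Sequence[str]], states: StateSpace
) -> TransitionModel:
    """Estimate the full chain: counts → row-normalized P, plus π."""
    counts = count_transitions(sessions, states)
    return TransitionModel(
        states=states,
        P=normalize(counts),
        pi=estimate_initial(sessions, states),
        n_sessions=len(sessions),
    )


def sequence_log_likelihood(
    model: TransitionModel,
    trail: Sequence[str],
    include_initial: bool = False,
) -> float:
    """Natural-log likelihood of a trail as the product of its step probabilities.

    The exit state is appended if absent, so a trail of pages
    ``[s_a, s_b]`` scores ``log p(a,b) + log p(b,exit)``.  Any
    zero-probability step yields ``-inf``.  By default the initial term
    ``log π`` is excluded, matching the product-of-transitions likelihood
    used for sequence clustering; ``include_initial=True`` adds it.
    """
    states = model.states
    trail = list(trail)
    if not trail or trail[-1] != states.exit_label:
        trail = trail + [states.exit_label]
    if len(trail) < 2:
        raise ValueError("trail must contain at least one state besides exit")
    ix = [states.index(p) for p in trail]
    total = 0.0
    if include_initial:
        p0 = model.pi[ix[0]]
        total += float(np.log(p0)) if p0 > 0 else -np.inf
    for a, b in zip(ix, ix[1:]):
        p = model.P[a, b]
        if p <= 0.0:
            return -np.inf
        total += float(np.log(p))
    return total


def _sampling_rows(model: TransitionModel) -> np.ndarray:
    """Rows renormalized by their sums for sampling.

    Tolerates matrices whose printed entries sum to 0.99–1.01 per row
    (2-decimal rounding); genuinely dangling rows are left zero and
    trigger an error if reached during simulation.
    """
    sums = model.P.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, model.P / np.where(sums == 0, 1.0, sums), 0.0)


def simulate_session(
    model: TransitionModel,
    rng: np.random.Generator | int | None = None,
    max_len: int = 100,
) -> SimulatedTrail:
    """Sample one session trail from the chain.

    The first state is drawn from π; successive states from the current
    row of P until exit is drawn or ``max_len`` page states have been
    emitted (in which case the trail is flagged truncated).  The returned
    trail excludes the exit state.  Reaching a dangling non-exit state is
    an error naming that state.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = model.states
    exit_ix = states.exit_index

    pi = model.pi.copy()
    pi[exit_ix] = 0.0
    if pi.sum() <= 0:
        raise ValueError("initial distribution has no mass on non-exit states")
    pi = pi / pi.sum()
    rows = _sampling_rows(model)

    current = int(rng.choice(states.n_states, p=pi))
    trail = [states.labels[current]]
    while len(trail) < max_len:
        row = rows[current]
        if row.sum() == 0.0:
            raise ValueError(
                f"state {states.labels[current]!r} has no outgoing transitions"
            )
        current = int(rng.choice(states.n_states, p=row))
        if current == exit_ix:
            return SimulatedTrail(trail=trail, truncated=False)
        trail.append(states.labels[current])
    return SimulatedTrail(trail=trail, truncated=True)


def simulate_trails(
    model: TransitionModel,
    n: int,
    rng: np.random.Generator | int | None = None,
    max_len: int = 100,
) -> list[list[str]]:
    """Sample ``n`` session trails (convenience wrapper over :func:`simulate_session`)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return [simulate_session(model, rng, max_len=max_len).trail for _ in range(n)]


def page_view_summary(sessions: Sequence[Session] | Sequence[Sequence[str]]) -> pd.DataFrame:
    """Per-page view counts and relative shares, sorted by views.

    Returns a frame indexed by page with columns ``views`` (absolute
    occurrences across all trails) and ``share`` (percentage of total
    views, reported to one decimal).
    """
    trails = _trails(sessions)
    if not trails:
        raise ValueError("no sessions to summarize")
    counts: dict[str, int] = {}
    for trail in trails:
        for page in trail:
            counts[page] = counts.get(page, 0) + 1
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=["views"])
    frame = frame.sort_values("views", ascending=False)
    frame["share"] = (frame["views"] / frame["views"].sum() * 100).round(1)
    frame.index.name = "page"
    return frame


def save_model(model: TransitionModel, dest: str | Path | IO[str]) -> None:
    """Persist a model as JSON (labels, P rows, π, metadata)."""
    doc = {
        "pages": list(model.states.pages),
        "exit_label": model.states.exit_label,
        "P": model.P.tolist(),
        "pi": model.pi.tolist(),
        "metadata": {
            "n_sessions": model.n_sessions,
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "software": "clickchain 0.1.0",
        },
    }
    text = json.dumps(doc, indent=1)
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def load_model(source: str | Path | IO[str]) -> TransitionModel:
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    doc = json.loads(text)
    states = StateSpace(pages=tuple(doc["pages"]), exit_label=doc["exit_label"])
    return TransitionModel(
        states=states,
        P=np.array(doc["P"], dtype=float),
        pi=np.array(doc["pi"], dtype=float),
        n_sessions=doc.get("metadata", {}).get("n_sessions"),
    )
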