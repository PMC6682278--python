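"""Synthetic app-log generation emulating the Start2Cycle field trial.

The generator produces ground-truth-labeled raw logs so every pipeline
stage (sessionization, chain fitting, clustering) can be tested without
any real data: 22 users by default, an overdispersed number of sessions
per user (negative-binomial, mean ≈ 37, SD ≈ 29), and per-session trails
simulated from one of three archetype chains (gamification, route
tracking, bug report).  Intra-session gaps are drawn strictly below the
30-minute sessionization threshold and inter-session gaps strictly above
it, so the true session partition is recoverable exactly.

The module also packages the published Start2Cycle transition matrix and
initial distribution as a reference model for fixtures and simulation.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .log_io import Dialect, LogEvent, RawLog, StateSpace
from .markov import TransitionModel, simulate_session

__all__ = [
    "START2CYCLE_PAGES",
    "GeneratorConfig",
    "GroundTruth",
    "GroundTruthSession",
    "start2cycle_reference_model",
    "make_archetype_chains",
    "generate_log",
    "config_from_yaml",
]

# Page order of the published transition matrix; exit state last.
START2CYCLE_PAGES = (
    "Trophies",
    "Bug report",
    "Coach",
    "Competition",
    "Personal",
    "Route",
    "Routes",
    "Team",
    "Track",
)


def start2cycle_reference_model() -> TransitionModel:
    """The published Start2Cycle chain: 9 pages + exit.

    The transition matrix holds the printed two-decimal probabilities
    verbatim (absent transitions as 0), so individual row sums lie within
    accumulated printed rounding of 1 rather than summing exactly.  The
    initial distribution puts 0.769 on Coach (the reported share of
    sessions starting there); the remaining 0.231 is an emulation choice
    split between Track (0.15) and Competition (0.081), the pages on
    which interrupted sessions most often resumed.
    """
    ref = importlib.resources.files("clickchain").joinpath("data/start2cycle_model.json")
    doc = json.loads(ref.read_text())
    states = StateSpace(pages=tuple(doc["pages"]), exit_label=doc["exit_label"])
    return TransitionModel(
        states=states,
        P=np.array(doc["P"], dtype=float),
        pi=np.array(doc["pi"], dtype=float),
        n_sessions=doc["metadata"]["n_sessions"],
    )


def _chain(states: StateSpace, rows: dict[str, dict[str, float]], pi: dict[str, float]) -> TransitionModel:
    n = states.n_states
    P = np.zeros((n, n))
    for src, targets in rows.items():
        for dst, p in targets.items():
            P[states.index(src), states.index(dst)] = p
    pi_vec = np.zeros(n)
    for page, p in pi.items():
        pi_vec[states.index(page)] = p
    return TransitionModel(states=states, P=P, pi=pi_vec)


def make_archetype_chains() -> dict[str, TransitionModel]:
    """Three well-separated session archetypes over the 9-page space.

    * **gamification** — Coach → Competition ↔ Team loops, then exit;
    * **route_tracking** — Coach → Track → Route ↔ Routes browsing
      (with an occasional Trophies visit), then exit;
    * **bug_report** — Coach → Personal → Bug report → Track, then exit.

    Separability is a design goal: an archetype must be recoverable from
    the transitions alone (the clustering likelihood ignores the initial
    distribution), so the Coach row — every archetype's usual first step —
    keeps only 0.05 exit mass and routes almost all probability toward
    that archetype's distinctive pages.  Later pages carry exit mass of
    0.25–0.6, which puts the mean trail length around five actions.  Each
    archetype's initial distribution is concentrated on Coach, with a
    small resume mass on Competition (gamification) and Track (route
    tracking), mirroring where interrupted sessions restart.  All values
    are design choices, not estimates.
    """
    states = StateSpace(pages=START2CYCLE_PAGES)
    gamification = _chain(
        states,
        rows={
            "Coach": {"Competition": 0.53, "Team": 0.42, "Exit": 0.05},
            "Competition": {"Team": 0.40, "Coach": 0.35, "Exit": 0.25},
            "Team": {"Competition": 0.40, "Coach": 0.35, "Exit": 0.25},
        },
        pi={"Coach": 0.9, "Competition": 0.1},
    )
    route_tracking = _chain(
        states,
        rows={
            "Coach": {"Track": 0.95, "Exit": 0.05},
            "Track": {"Route": 0.55, "Routes": 0.15, "Coach": 0.05, "Exit": 0.25},
            "Route": {"Routes": 0.50, "Track": 0.10, "Coach": 0.15, "Exit": 0.25},
            "Routes": {"Route": 0.50, "Coach": 0.15, "Trophies": 0.10, "Exit": 0.25},
            "Trophies": {"Coach": 0.40, "Exit": 0.60},
        },
        pi={"Coach": 0.9, "Track": 0.1},
    )
    bug_report = _chain(
        states,
        rows={
            "Coach": {"Personal": 0.95, "Exit": 0.05},
            "Personal": {"Bug report": 0.70, "Coach": 0.05, "Exit": 0.25},
            "Bug report": {"Track": 0.60, "Personal": 0.10, "Exit": 0.30},
            "Track": {"Coach": 0.40, "Exit": 0.60},
        },
        pi={"Coach": 1.0},
    )
    return {
        "gamification": gamification,
        "route_tracking": route_tracking,
        "bug_report": bug_report,
    }


@dataclasses.dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic field-trial log generator.

    Defaults emulate the 25-day trial: 22 users, negative-binomial session
    counts (mean 37, SD ≈ 29.35), trails from the three archetype chains,
    intra-session gaps of 5–120 s and inter-session gaps of 45 min – 16 h
    (keeping both strictly on their side of the 30-minute sessionization
    threshold).
    """

    n_users: int = 22
    sessions_per_user_mean: float = 37.0
    sessions_per_user_sd: float = 29.35
    archetype_chains: dict[str, TransitionModel] | None = None
    mixture_weights: dict[str, float] | None = None
    intra_session_gap_seconds: tuple[float, float] = (5.0, 120.0)
    inter_session_gap_minutes: tuple[float, float] = (45.0, 960.0)
    start_time: pd.Timestamp = pd.Timestamp("2017-09-01T08:00:00Z")
    max_trail_len: int = 100
    seed: int = 0

    def resolved_chains(self) -> dict[str, TransitionModel]:
        return self.archetype_chains or make_archetype_chains()

    def resolved_weights(self) -> dict[str, float]:
        if self.mixture_weights is not None:
            return self.mixture_weights
        return {"gamification": 0.35, "route_tracking": 0.45, "bug_report": 0.20}

    def validate(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        chains = self.resolved_chains()
        weights = self.resolved_weights()
        if set(weights) != set(chains):
            raise ValueError("mixture_weights keys must match archetype_chains")
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        spaces = {c.states.labels for c in chains.values()}
        if len(spaces) != 1:
            raise ValueError("all archetype chains must share one state space")
        lo_intra, hi_intra = self.intra_session_gap_seconds
        lo_inter, hi_inter = self.inter_session_gap_minutes
        if not (0 <= lo_intra <= hi_intra and 0 < lo_inter <= hi_inter):
            raise ValueError("gap ranges must be non-empty and non-negative")
        if lo_inter * 60.0 <= hi_intra:
            raise ValueError(
                "minimum inter-session gap must exceed the maximum intra-session gap"
            )


@dataclasses.dataclass
class GroundTruthSession:
    user_id: str
    session_index: int
    archetype: str
    trail: list[str]


@dataclasses.dataclass
class GroundTruth:
    """True per-session labels and the per-event session index."""

    sessions: list[GroundTruthSession]
    event_session_index: list[int]  # parallel to the emitted event stream

    def archetype_labels(self) -> list[str]:
        return [s.archetype for s in self.sessions]


def generate_log(config: GeneratorConfig) -> tuple[RawLog, GroundTruth]:
    """Generate a labeled synthetic raw log; deterministic given ``config.seed``.

    For each user a session count is drawn, then per session an archetype
    and a trail simulated from that archetype's chain; timestamps place
    consecutive events within a session closer than the sessionization
    threshold and consecutive sessions further apart than it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chains = config.resolved_chains()
    weights = config.resolved_weights()
    names = list(chains)
    probs = np.array([weights[n] for n in names])

    mean, sd = config.sessions_per_user_mean, config.sessions_per_user_sd
    var = sd**2
    if sd == 0:
        r = p = None  # fixed count per user
    elif var <= mean:
        raise ValueError(
            "session-count SD must exceed sqrt(mean) for overdispersion "
            "(use sd=0 for a fixed count)"
        )
    else:
        r = mean**2 / (var - mean)
        p = r / (r + mean)

    lo_intra, hi_intra = config.intra_session_gap_seconds
    lo_inter, hi_inter = config.inter_session_gap_minutes
    width = max(2, len(str(config.n_users)))

    events: list[LogEvent] = []
    truth_sessions: list[GroundTruthSession] = []
    event_session_index: list[int] = []

    for u in range(config.n_users):
        user_id = f"u{u + 1:0{width}d}"
        n_sessions = (
            max(1, int(round(mean)))
            if r is None
            else max(1, int(rng.negative_binomial(r, p)))
        )
        # stagger users across the first day of the window
        t = config.start_time + pd.Timedelta(seconds=float(rng.uniform(0, 86400)))
        for s in range(n_sessions):
            archetype = names[int(rng.choice(len(names), p=probs))]
            trail = simulate_session(
                chains[archetype], rng, max_len=config.max_trail_len
            ).trail
            session_id = len(truth_sessions)
            for k, page in enumerate(trail):
                if k > 0:
                    t = t + pd.Timedelta(seconds=float(rng.uniform(lo_intra, hi_intra)))
                events.append(LogEvent(user_id=user_id, timestamp=t, page=page))
                event_session_index.append(session_id)
            truth_sessions.append(
                GroundTruthSession(
                    user_id=user_id, session_index=s, archetype=archetype, trail=trail
                )
            )
            t = t + pd.Timedelta(minutes=float(rng.uniform(lo_inter, hi_inter)))
    return (
        RawLog(events=events, dialect=Dialect.EVENT),
        GroundTruth(sessions=truth_sessions, event_session_index=event_session_index),
    )


def config_from_yaml(source: str | Path) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a YAML mapping of its scalar fields.

    Archetype chains themselves are not expressible in YAML; the packaged
    defaults are used.
    """
    doc = yaml.safe_load(Path(source).read_text()) or {}
    kwargs = {}
    scalar = {
        "n_users",
        "sessions_per_user_mean",
        "sessions_per_user_sd",
        "max_trail_len",
        "seed",
    }
    for key, value in doc.items():
        if key in scalar:
            kwargs[key] = value
        elif key == "mixture_weights":
            kwargs[key] = dict(value)
        elif key in {"intra_session_gap_seconds", "inter_session_gap_minutes"}:
            kwargs[key] = tuple(value)
        elif key == "start_time":
            kwargs[key] = pd.Timestamp(value)
        else:
            raise ValueError(f"unknown generator config key {key!r}")
    return GeneratorConfig(**kwargs)
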