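"""Hard-EM clustering of session trails into a mixture of Markov chains.

Each of the K clusters is represented by its own transition matrix over
the shared state space.  The algorithm alternates:

1. assign every trail uniformly at random to one of K clusters;
2. build each cluster's chain from its assigned trails (M-step), adding a
   pseudocount to every non-exit-row cell before normalization so that a
   trail containing a transition unseen in a cluster still has nonzero
   likelihood there;
3. reassign every trail to the cluster under which its product-of-step
   probabilities likelihood is maximal (E-step, computed in log space,
   ties broken by lowest cluster index);
4. repeat until the assignment vector is identical to the previous
   iteration's, or ``max_iter`` is reached.

This is classification EM (hard assignments), not soft-responsibility EM.
A cluster left empty by reassignment is re-seeded with the single worst
fitting trail so K stays constant.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .log_io import StateSpace
from .markov import TransitionModel, estimate_initial, _trails
from .sessionizer import Session

__all__ = ["ClusterModel", "cluster_sequences", "classify", "total_log_likelihood"]


@dataclasses.dataclass
class ClusterModel:
    """K fitted cluster chains with the trail-to-cluster assignment."""

    K: int
    chains: list[TransitionModel]
    assignments: np.ndarray  # per-session cluster index in {0..K-1}
    n_iter: int
    converged: bool
    seed: int | None
    pseudocount: float
    log_likelihood: float  # total log-likelihood of trails under assigned clusters
    trace: list[float]  # objective after each E-step


def _smoothed_chain(
    index_trails: list[np.ndarray], states: StateSpace, pseudocount: float
) -> np.ndarray:
    """Per-cluster transition matrix: counts + pseudocount on every
    non-exit-row cell (exit column included), then row normalization.

    Trails arrive as state-index arrays already terminated by exit.
    """
    n = states.n_states
    counts = np.zeros((n, n))
    for ix in index_trails:
        np.add.at(counts, (ix[:-1], ix[1:]), 1.0)
    counts[: states.n_pages, :] += pseudocount
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, counts / np.where(sums == 0, 1.0, sums), 0.0)


def _log_matrix(P: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(P)


def _trail_loglik(logP: np.ndarray, ix: np.ndarray) -> float:
    return float(logP[ix[:-1], ix[1:]].sum())


def _em_run(
    index_trails: list[np.ndarray],
    states: StateSpace,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    pseudocount: float,
) -> tuple[np.ndarray, list[np.ndarray], int, bool, float, list[float]]:
    n = len(index_trails)
    assignments = rng.integers(0, K, size=n)
    trace: list[float] = []
    converged = False
    n_iter = 0
    loglik = np.empty((n, K))
    for n_iter in range(1, max_iter + 1):
        chains = [
            _smoothed_chain(
                [ix for ix, a in zip(index_trails, assignments) if a == k],
                states,
                pseudocount,
            )
            for k in range(K)
        ]
        log_chains = [_log_matrix(P) for P in chains]
        for i, ix in enumerate(index_trails):
            for k in range(K):
                loglik[i, k] = _trail_loglik(log_chains[k], ix)
        new_assignments = loglik.argmax(axis=1)

        # re-seed empty clusters with the single worst-fitting trail
        for k in range(K):
            if not (new_assignments == k).any():
                fit_under_assigned = loglik[np.arange(n), new_assignments]
                movable = np.array(
                    [np.sum(new_assignments == new_assignments[i]) > 1 for i in range(n)]
                )
                candidates = np.where(movable)[0]
                worst = candidates[fit_under_assigned[candidates].argmin()]
                new_assignments[worst] = k

        trace.append(float(loglik[np.arange(n), new_assignments].sum()))
        if (new_assignments == assignments).all():
            converged = True
            break
        assignments = new_assignments
    total = trace[-1]
    chains = [
        _smoothed_chain(
            [ix for ix, a in zip(index_trails, assignments) if a == k],
            states,
            pseudocount,
        )
        for k in range(K)
    ]
    return assignments, chains, n_iter, converged, total, trace


def cluster_sequences(
    sessions: Sequence[Session] | Sequence[Sequence[str]],
    K: int,
    seed: int | None = None,
    max_iter: int = 100,
    pseudocount: float = 0.5,
    states: StateSpace | None = None,
    n_restarts: int = 1,
) -> ClusterModel:
    """Cluster session trails into K Markov-chain components by hard EM.

    Parameters
    ----------
    sessions
        Sessions or bare trails; the exit state is appended internally
        when scoring and counting.
    K
        Number of clusters (1 ≤ K ≤ number of sessions).
    seed
        Seeds both the random initial assignment and restart spawning;
        identical seed and input give an identical model.
    max_iter
        Iteration cap; if reached without a repeated assignment vector the
        model is returned with ``converged=False``.
    pseudocount
        Smoothing constant added to every admissible transition cell of a
        cluster chain before normalization (must be > 0 for reassignment
        to be well defined on sparse clusters).
    states
        Shared state space; inferred from the trails when omitted.
    n_restarts
        Independent EM runs; the one with the highest total assigned
        log-likelihood is returned.
    """
    trails = _trails(sessions)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(trails):
        raise ValueError(f"K={K} exceeds the number of sessions ({len(trails)})")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if states is None:
        seen: dict[str, None] = {}
        for t in trails:
            for p in t:
                seen.setdefault(p)
        states = StateSpace(pages=tuple(seen))

    exit_ix = states.exit_index
    index_trails = [
        np.array([states.index(p) for p in t] + [exit_ix]) for t in trails
    ]

    root = np.random.SeedSequence(seed)
    best = None
    for child in root.spawn(n_restarts):
        rng = np.random.default_rng(child)
        run = _em_run(index_trails, states, K, rng, max_iter, pseudocount)
        if best is None or run[4] > best[4]:
            best = run
    assignments, chains, n_iter, converged, total, trace = best

    chain_models = []
    for k in range(K):
        member_trails = [t for t, a in zip(trails, assignments) if a == k]
        pi = (
            estimate_initial(member_trails, states)
            if member_trails
            else np.zeros(states.n_states)
        )
        chain_models.append(
            TransitionModel(states=states, P=chains[k], pi=pi, n_sessions=len(member_trails))
        )
    return ClusterModel(
        K=K,
        chains=chain_models,
        assignments=assignments,
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        pseudocount=pseudocount,
        log_likelihood=total,
        trace=trace,
    )


def classify(
    model: ClusterModel, trail: Sequence[str]
) -> tuple[int, np.ndarray]:
    """Assign an unseen trail to its maximum-likelihood cluster.

    Returns the winning cluster index and the full per-cluster
    log-likelihood vector; ties break to the lowest index.
    """
    states = model.chains[0].states
    trail = list(trail)
    if not trail or trail[-1] != states.exit_label:
        trail = trail + [states.exit_label]
    ix = np.array([states.index(p) for p in trail])
    logliks = np.array(
        [_trail_loglik(_log_matrix(chain.P), ix) for chain in model.chains]
    )
    return int(logliks.argmax()), logliks


def total_log_likelihood(
    model: ClusterModel, sessions: Sequence[Session] | Sequence[Sequence[str]]
) -> float:
    """Sum over sessions of the log-likelihood under each one's assigned cluster."""
    trails = _trails(sessions)
    states = model.chains[0].states
    exit_ix = states.exit_index
    total = 0.0
    for trail, k in zip(trails, model.assignments):
        ix = np.array([states.index(p) for p in trail] + [exit_ix])
        total += _trail_loglik(_log_matrix(model.chains[k].P), ix)
    return total
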