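"""Exact linear-algebraic machinery for successor representations.

This module holds the closed-form objects the rest of the package is
checked against: stationary distributions, the time-reversed (backward)
chain ``P^backward = Pi^{-1} P^T Pi``, blends ``P_{alpha,beta}`` of forward
and backward transitions, the successor-representation matrix
``(I - gamma P)^{-1}``, detailed-balance tests, and the closed-form SR of a
shortest-path navigation policy.

Conventions
-----------
Transition matrices are row-stochastic with the *forward* convention
``P[s, s'] = p(s' | s)``.  Any expectation of feature columns therefore
uses ``P`` acting from the left on state-indexed vectors, i.e. ``P @ f``
for a state function ``f``, and ``P.T`` acting on feature matrices whose
columns are states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import isinf
from typing import NamedTuple

import networkx as nx
import numpy as np

__all__ = [
    "TransitionModel",
    "RuleParameters",
    "SuccessorMatrix",
    "stationary_distribution",
    "backward_transitions",
    "blend_transitions",
    "successor_matrix",
    "is_reversible",
    "geometric_sr_entry",
    "uniform_policy_distance",
]

_ROW_TOL = 1e-10


class RuleParameters(NamedTuple):
    """Weights (alpha, beta) of the temporally parametrized learning rule.

    ``alpha`` weighs the forward-in-time (predictive) term, ``beta`` the
    backward-in-time (postdictive) term.  ``alpha = beta`` gives a rule
    invariant under time reversal; ``alpha = -beta`` is the degenerate
    antisymmetric case for which no blended chain exists.
    """

    alpha: float
    beta: float


@dataclass(frozen=True)
class TransitionModel:
    """A finite, time-homogeneous Markov chain given by a row-stochastic matrix."""

    P: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError(f"transition matrix must be square, got shape {P.shape}")
        if np.any(P < 0):
            raise ValueError("transition probabilities must be non-negative")
        rows = P.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _ROW_TOL):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(
                f"row {bad} sums to {rows[bad]!r}, not 1 (tolerance {_ROW_TOL})"
            )
        object.__setattr__(self, "P", P)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != P.shape[0]:
                raise ValueError("number of labels must match number of states")
            object.__setattr__(self, "labels", labels)

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    # -- serialization ---------------------------------------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        labels = list(self.labels) if self.labels else [str(i) for i in range(self.n_states)]
        pd.DataFrame(self.P, index=labels, columns=labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TransitionModel":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), labels=tuple(map(str, df.columns)))

    def to_json(self, path) -> None:
        s, t = np.nonzero(self.P)
        payload = {
            "n_states": self.n_states,
            "labels": list(self.labels) if self.labels else None,
            "triplets": [[int(i), int(j), float(self.P[i, j])] for i, j in zip(s, t)],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TransitionModel":
        with open(path) as fh:
            payload = json.load(fh)
        n = int(payload["n_states"])
        P = np.zeros((n, n))
        for i, j, v in payload["triplets"]:
            P[int(i), int(j)] = float(v)
        labels = payload.get("labels")
        return cls(P, labels=tuple(labels) if labels else None)


@dataclass(frozen=True)
class SuccessorMatrix:
    """Discounted expected future occupancies ``M = (I - gamma P)^{-1}``."""

    M: np.ndarray
    gamma: float

    @property
    def n_states(self) -> int:
        return self.M.shape[0]


def _support_graph(P: np.ndarray) -> nx.DiGraph:
    G = nx.DiGraph()
    G.add_nodes_from(range(P.shape[0]))
    G.add_edges_from(zip(*np.nonzero(P)))
    return G


def _check_ergodic(tm: TransitionModel) -> None:
    G = _support_graph(tm.P)
    if not nx.is_strongly_connected(G):
        raise ValueError(
            "chain is reducible: support graph is not strongly connected, "
            "no unique stationary distribution exists"
        )
    if not nx.is_aperiodic(G):
        raise ValueError(
            "chain is periodic: gcd of support-graph cycle lengths exceeds 1"
        )


def stationary_distribution(tm: TransitionModel) -> np.ndarray:
    """Unique stationary distribution pi of an ergodic chain, ``pi^T P = pi^T``.

    Solved deterministically as the linear system ``(I - P^T) pi = 0`` with a
    normalization row appended, not by power iteration.

    Raises
    ------
    ValueError
        If the chain is reducible or periodic.
    """
    _check_ergodic(tm)
    n = tm.n_states
    A = np.vstack([np.eye(n) - tm.P.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    residual = np.max(np.abs(pi @ tm.P - pi))
    if residual > 1e-8:
        raise ValueError(f"stationary solve failed, residual {residual:g}")
    return pi


def backward_transitions(
    tm: TransitionModel, pi: np.ndarray | None = None
) -> TransitionModel:
    """Transition matrix of the time-reversed chain, ``Pi^{-1} P^T Pi``.

    The backward chain has entries ``p(S_t = s' | S_{t+1} = s)`` evaluated at
    stationarity; it is row-stochastic and shares the stationary
    distribution of the forward chain.
    """
    if pi is None:
        pi = stationary_distribution(tm)
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("backward chain undefined: zero stationary mass on a state")
    Pb = (tm.P * pi[:, None]).T / pi[:, None]
    # renormalise away float round-off so the invariant holds exactly
    Pb = Pb / Pb.sum(axis=1, keepdims=True)
    return TransitionModel(Pb, labels=tm.labels)


def blend_transitions(
    tm: TransitionModel, rule: RuleParameters | tuple[float, float]
) -> TransitionModel:
    """Blended chain ``P_{alpha,beta}``, a weighted sum of forward and backward.

    ``P_{a,b} = a/(a+b) P^forward + b/(a+b) P^backward``.  Only the ratio
    alpha : beta matters.  For ``alpha = beta`` the blend is the symmetrized
    chain ``(P + P^backward)/2``, which satisfies detailed balance.

    Raises
    ------
    ValueError
        If ``alpha + beta == 0`` (the blend is undefined; learning does not
        converge at this boundary).
    """
    alpha, beta = rule
    total = alpha + beta
    if abs(total) < 1e-12:
        raise ValueError(
            "blend undefined for alpha + beta = 0: the antisymmetric boundary "
            "case has no convergent representation"
        )
    pi = stationary_distribution(tm)
    Pb = backward_transitions(tm, pi).P
    P = (alpha / total) * tm.P + (beta / total) * Pb
    if np.any(P < 0):
        raise ValueError(
            "blend produced negative probabilities; use parameters where the "
            "positive weight dominates in absolute value"
        )
    return TransitionModel(P / P.sum(axis=1, keepdims=True), labels=tm.labels)


def successor_matrix(tm: TransitionModel, gamma: float) -> SuccessorMatrix:
    """Successor representation ``M = (I - gamma P)^{-1}`` (Neumann series).

    Equals ``sum_k gamma^k P^k``; requires ``0 <= gamma < 1``.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"discount must satisfy 0 <= gamma < 1, got {gamma}")
    n = tm.n_states
    M = np.linalg.inv(np.eye(n) - gamma * tm.P)
    return SuccessorMatrix(M, gamma)


def is_reversible(tm: TransitionModel, tol: float = 1e-10) -> bool:
    """Detailed balance test: ``pi(s) P[s,s'] == pi(s') P[s',s]`` for all pairs."""
    pi = stationary_distribution(tm)
    flow = pi[:, None] * tm.P
    return bool(np.max(np.abs(flow - flow.T)) <= tol)


def geometric_sr_entry(
    distance: float,
    gamma: float,
    is_target: bool = False,
    is_self: bool = False,
    return_cycle: float | None = None,
) -> float:
    """Closed-form SR entry for an optimal deterministic navigation policy.

    For a policy that only follows shortest paths to a target, non-target
    states are visited at most once and the SR entry for a pair at graph
    distance ``d`` is geometric in the discount:

    * self, non-target diagonal: 1 (the current-occupancy delta);
    * off every shortest path, or unreachable (``d = inf``): 0;
    * on-path, non-target: ``gamma^d``;
    * target column: ``gamma^d / (1 - gamma^L)`` where ``L`` is the length
      of the shortest cycle returning to the target (``return_cycle``,
      defaulting to ``d``); the target's own diagonal adds the
      current-occupancy 1, i.e. ``1 + gamma^L / (1 - gamma^L)``.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"discount must satisfy 0 <= gamma < 1, got {gamma}")
    if not isinf(distance) and distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    if isinf(distance):
        return 1.0 if is_self else 0.0
    if is_target:
        # gamma^d / (1 - gamma^L); at the target itself (d = 0) this already
        # contains the current-occupancy delta: 1 + gamma^L / (1 - gamma^L)
        L = distance if return_cycle is None else return_cycle
        if L <= 0:
            raise ValueError("target recurrence requires a positive return-cycle length")
        return gamma ** distance / (1.0 - gamma ** L)
    if is_self:
        return 1.0
    return gamma ** distance


def uniform_policy_distance(
    tm: TransitionModel, uniform_tm: TransitionModel
) -> float:
    """Stationary-weighted mean KL divergence from a chain to the uniform policy.

    ``D = sum_s pi(s) KL(P[s, :] || U[s, :])`` with ``0 log 0 = 0``.  Used to
    quantify the claim that the symmetrized chain is always at least as close
    to the uniform-policy chain as the observed one.
    """
    if tm.n_states != uniform_tm.n_states:
        raise ValueError("chains must share the same state set")
    P, U = tm.P, uniform_tm.P
    if np.any((P > 0) & (U == 0)):
        raise ValueError("mismatched supports: chain uses an edge absent from the graph")
    pi = stationary_distribution(tm)
    mask = P > 0
    terms = np.zeros_like(P)
    terms[mask] = P[mask] * np.log(P[mask] / U[mask])
    return float(pi @ terms.sum(axis=1))
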