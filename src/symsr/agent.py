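"""Tabular successor-representation agent with the generalized TD rule.

The agent maintains a matrix estimate ``M`` of the successor
representation and a reward vector ``w``.  On a transition ``s -> s'`` the
rows of both states are updated with forward weight ``alpha`` and backward
weight ``beta``:

    dM[s , v] = alpha (1{v = s } + gamma M[s', v] - M[s , v])
    dM[s', v] = beta  (1{v = s'} + gamma M[s , v] - M[s', v])

``(alpha, beta) = (1, 0)`` is classical SR TD-learning, ``(1/2, 1/2)`` the
time-symmetric rule, and intermediate values interpolate.  Variants add
per-step noise to the parameters or a frozen per-state-pair heterogeneity.
Actions are chosen by softmax over ``q(s, a) = (M w)(s'(a))`` computed
through a known deterministic world model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .envs import ActionModel, graph_distances

__all__ = [
    "SRAgentParams",
    "SRAgentState",
    "EpisodeLog",
    "NavigationTask",
    "td_update",
    "td_update_noisy",
    "td_update_heterogeneous",
    "td_fixed_policy_estimate",
    "logs_to_frame",
    "update_reward",
    "q_values",
    "select_action",
    "policy_entropy",
    "run_episode",
    "train",
    "generalization_trial",
    "SuccessorAgent",
    "AgentResults",
]


@dataclass(frozen=True)
class SRAgentParams:
    """Learning-rule weights and hyperparameters of the SR agent.

    ``variant`` selects the update rule: ``fixed`` (constant alpha/beta),
    ``noisy`` (i.i.d. Gaussian noise of scale ``noise_sigma`` added to both
    parameters at every step), or ``heterogeneous`` (a frozen field of
    per-pair parameters ``|N(mu, hetero_sigma)|``).

    ``temperature`` scales the softmax over q-values; the default 0.01
    gives a near-greedy policy with residual softmax smoothing, which lets
    a trained agent actually exploit its value estimates (q-value
    differences decay like ``gamma^d`` and are far below 1 for distant
    targets).  ``lr_w`` defaults to 1, i.e. the reward estimate at the
    visited state is overwritten by the observed reward.
    """

    alpha: float = 1.0
    beta: float = 0.0
    lr: float = 0.1
    gamma: float = 0.7
    temperature: float = 0.01
    variant: str = "fixed"
    noise_sigma: float = 0.1
    hetero_means: tuple[float, float] = (1.0, 0.0)
    hetero_sigma: float = 0.1
    lr_w: float | None = 1.0

    def __post_init__(self) -> None:
        if self.variant not in ("fixed", "noisy", "heterogeneous"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")

    @property
    def reward_lr(self) -> float:
        return self.lr if self.lr_w is None else self.lr_w

    @classmethod
    def interpolated(cls, s: float, **kwargs) -> "SRAgentParams":
        """Rule on the classical-to-symmetric path: alpha = 1/(1+s), beta = s/(1+s)."""
        if s < 0:
            raise ValueError("interpolation parameter s must be >= 0")
        return cls(alpha=1.0 / (1.0 + s), beta=s / (1.0 + s), **kwargs)


@dataclass
class SRAgentState:
    """SR estimate, reward vector and (optionally) heterogeneous parameters."""

    M: np.ndarray
    w: np.ndarray
    alpha_field: np.ndarray | None = None
    beta_field: np.ndarray | None = None

    @classmethod
    def initial(
        cls,
        n_states: int,
        params: SRAgentParams | None = None,
        rng: np.random.Generator | None = None,
    ) -> "SRAgentState":
        """Identity SR (the untrained value function is the immediate reward)."""
        state = cls(np.eye(n_states), np.zeros(n_states))
        if params is not None and params.variant == "heterogeneous":
            if rng is None:
                raise ValueError("heterogeneous initialization needs an rng")
            mu_a, mu_b = params.hetero_means
            state.alpha_field = np.abs(
                rng.normal(mu_a, params.hetero_sigma, size=(n_states, n_states))
            )
            state.beta_field = np.abs(
                rng.normal(mu_b, params.hetero_sigma, size=(n_states, n_states))
            )
        return state


@dataclass(frozen=True)
class EpisodeLog:
    episode: int
    steps: int
    start: int
    target: int
    suboptimality: float
    entropy: float
    terminal: bool


def _apply_td(
    state: SRAgentState,
    s: int,
    s_next: int,
    gamma: float,
    lr: float,
    alpha_row,
    beta_row,
) -> None:
    """Shared row update; alpha_row/beta_row are scalars or length-n vectors."""
    M = state.M
    row_s = M[s].copy()
    row_s1 = M[s_next].copy()
    d_s = gamma * row_s1 - row_s
    d_s[s] += 1.0
    d_s1 = gamma * row_s - row_s1
    d_s1[s_next] += 1.0
    M[s] += lr * alpha_row * d_s
    M[s_next] += lr * beta_row * d_s1


def td_update(
    state: SRAgentState, s: int, s_next: int, params: SRAgentParams, lr: float | None = None
) -> SRAgentState:
    """Generalized TD update of the SR estimate; only rows s and s' change."""
    _apply_td(state, s, s_next, params.gamma, lr if lr is not None else params.lr,
              params.alpha, params.beta)
    return state


def td_update_noisy(
    state: SRAgentState,
    s: int,
    s_next: int,
    params: SRAgentParams,
    rng: np.random.Generator,
) -> SRAgentState:
    """TD update with fresh i.i.d. noise added to both rule parameters."""
    na, nb = rng.normal(0.0, params.noise_sigma, size=2) if params.noise_sigma > 0 else (0.0, 0.0)
    _apply_td(state, s, s_next, params.gamma, params.lr, params.alpha + na, params.beta + nb)
    return state


def td_update_heterogeneous(
    state: SRAgentState, s: int, s_next: int, params: SRAgentParams
) -> SRAgentState:
    """TD update with the frozen per-pair parameter fields alpha(u, v), beta(u, v)."""
    if state.alpha_field is None or state.beta_field is None:
        raise ValueError("heterogeneous parameters not initialized")
    _apply_td(
        state, s, s_next, params.gamma, params.lr,
        state.alpha_field[s], state.beta_field[s_next],
    )
    return state


def _td_dispatch(
    state: SRAgentState, s: int, s_next: int, params: SRAgentParams, rng
) -> None:
    if params.variant == "noisy":
        td_update_noisy(state, s, s_next, params, rng)
    elif params.variant == "heterogeneous":
        td_update_heterogeneous(state, s, s_next, params)
    else:
        td_update(state, s, s_next, params)


def td_fixed_policy_estimate(
    tm,
    rule: tuple[float, float],
    gamma: float,
    T: int = 50_000,
    seed: int | None = None,
    anneal_c: float = 2.0,
    avg_frac: float = 0.5,
) -> np.ndarray:
    """TD estimate of the SR under a frozen policy-induced chain.

    Samples ``T`` transitions from ``tm``, applies the generalized
    (alpha, beta) update with a per-state annealed learning rate
    ``c / (c + visits(s))``, and returns the Polyak (tail) average of the
    estimate over the last ``1 - avg_frac`` fraction of steps.  Converges
    to ``(I - gamma P_{alpha,beta})^{-1}``.
    """
    from .envs import sample_trajectory

    n = tm.n_states
    params = SRAgentParams(alpha=rule[0], beta=rule[1], gamma=gamma, lr=1.0)
    state = SRAgentState.initial(n)
    traj = sample_trajectory(tm, T, seed=seed)
    visits = np.zeros(n)
    avg = np.zeros((n, n))
    n_avg = 0
    cut = int(T * avg_frac)
    for t, (s, s1) in enumerate(zip(traj.states[:-1], traj.states[1:])):
        s, s1 = int(s), int(s1)
        visits[s] += 1
        td_update(state, s, s1, params, lr=anneal_c / (anneal_c + visits[s]))
        if t >= cut:
            avg += state.M
            n_avg += 1
    return avg / n_avg


def update_reward(state: SRAgentState, s: int, r: float, lr_w: float) -> SRAgentState:
    """Exponential update of the reward estimate at the observed state."""
    state.w[s] += lr_w * (r - state.w[s])
    return state


def q_values(state: SRAgentState, s: int, actions: ActionModel) -> np.ndarray:
    """q(s, a) = sum_{s''} w(s'') M[s'(a), s''] — the value of the successor state."""
    nxt = actions.next_state[s]
    return state.M[nxt] @ state.w


def select_action(
    q: np.ndarray, temperature: float, rng: np.random.Generator
) -> int:
    """Sample from softmax(q / temperature); temperature 0 is uniform-tie argmax."""
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("q-values must be finite")
    if temperature <= 0:
        best = np.flatnonzero(q >= q.max() - 1e-12)
        return int(best[rng.integers(len(best))])
    z = q / temperature
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(len(q), p=p))


def policy_entropy(
    state: SRAgentState, actions: ActionModel, temperature: float = 1.0
) -> float:
    """Shannon entropy of the softmax policy, averaged over all states (nats)."""
    v = state.M @ state.w
    q = v[actions.next_state]  # (n_states, n_actions)
    if temperature <= 0:
        raise ValueError("entropy of the zero-temperature policy is degenerate; use temperature > 0")
    z = q / temperature
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return float(terms.sum(axis=1).mean())


# ---------------------------------------------------------------------------
# episodes and training protocols
# ---------------------------------------------------------------------------

@dataclass
class NavigationTask:
    """A deterministic navigation environment with a designated target state.

    A unit reward is delivered on arrival at ``target``; episodes start
    uniformly over the other states and end at the target or after
    ``max_steps`` steps.
    """

    actions: ActionModel
    target: int
    max_steps: int = 400
    _distances: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.actions.n_states

    @property
    def distances(self) -> np.ndarray:
        if self._distances is None:
            self._distances = graph_distances(self.actions)
        return self._distances

    def optimal_steps(self, start: int) -> float:
        return float(self.distances[start, self.target])

    def start_states(self) -> np.ndarray:
        """Non-target states from which the target is reachable."""
        d = self.distances[:, self.target]
        ok = np.isfinite(d) & (np.arange(self.n_states) != self.target)
        return np.flatnonzero(ok)

    def with_target(self, target: int) -> "NavigationTask":
        return NavigationTask(self.actions, target, self.max_steps, self._distances)


def run_episode(
    state: SRAgentState,
    task: NavigationTask,
    params: SRAgentParams,
    rng: np.random.Generator,
    episode: int = 0,
    learn_M: bool = True,
    learn_w: bool = True,
    start: int | None = None,
) -> EpisodeLog:
    """Run one episode; updates M (per variant) and w in place along the way."""
    starts = task.start_states()
    if len(starts) == 0:
        raise ValueError("target unreachable from every other state")
    s = int(start) if start is not None else int(starts[rng.integers(len(starts))])
    steps = 0
    start_state = s
    terminal = False
    while steps < task.max_steps:
        q = q_values(state, s, task.actions)
        a = select_action(q, params.temperature, rng)
        s_next = int(task.actions.next_state[s, a])
        r = 1.0 if s_next == task.target else 0.0
        if learn_M:
            _td_dispatch(state, s, s_next, params, rng)
        if learn_w:
            update_reward(state, s_next, r, params.reward_lr)
        s = s_next
        steps += 1
        if s == task.target:
            terminal = True
            break
    subopt = steps - task.optimal_steps(start_state)
    entropy = policy_entropy(state, task.actions, max(params.temperature, 1e-9))
    return EpisodeLog(episode, steps, start_state, task.target, subopt, entropy, terminal)


def train(
    state: SRAgentState,
    task: NavigationTask,
    params: SRAgentParams,
    rng: np.random.Generator,
    stop_rule: tuple = ("fixed_episodes", 400),
    learn_M: bool = True,
    hard_cap: int = 3000,
) -> list[EpisodeLog]:
    """Train until the stop rule fires and return the full episode log.

    ``stop_rule`` is ``("fixed_episodes", N)`` or ``("accuracy", window, tol)``
    — stop once the mean suboptimality over the last ``window`` episodes
    drops below ``tol`` (defaults 8 and 2).  If the accuracy rule never
    fires within ``hard_cap`` episodes the run stops there and the last log
    entry simply reflects that (flagged by length == hard_cap).
    """
    kind = stop_rule[0]
    logs: list[EpisodeLog] = []
    if kind == "fixed_episodes":
        for ep in range(int(stop_rule[1])):
            logs.append(run_episode(state, task, params, rng, ep, learn_M=learn_M))
        return logs
    if kind != "accuracy":
        raise ValueError(f"unknown stop rule {kind!r}")
    window = int(stop_rule[1]) if len(stop_rule) > 1 else 8
    tol = float(stop_rule[2]) if len(stop_rule) > 2 else 2.0
    for ep in range(hard_cap):
        logs.append(run_episode(state, task, params, rng, ep, learn_M=learn_M))
        if len(logs) >= window:
            recent = np.mean([lg.suboptimality for lg in logs[-window:]])
            if recent < tol:
                break
    return logs


def generalization_trial(
    state: SRAgentState,
    task: NavigationTask,
    new_target: int,
    params: SRAgentParams,
    rng: np.random.Generator,
    episodes: int = 100,
    reset_w: bool = True,
) -> list[EpisodeLog]:
    """Probe generalization: freeze M, relearn only the reward vector.

    The reward vector is reset (default) and the agent runs ``episodes``
    episodes toward ``new_target`` with the SR frozen; logs report steps
    and suboptimality against the directed shortest-path distance.
    """
    if reset_w:
        state.w[:] = 0.0
    new_task = task.with_target(int(new_target))
    return [
        run_episode(state, new_task, params, rng, ep, learn_M=False)
        for ep in range(episodes)
    ]


def logs_to_frame(logs: Sequence[EpisodeLog]) -> pd.DataFrame:
    return pd.DataFrame([lg.__dict__ for lg in logs])


# ---------------------------------------------------------------------------
# model / results presentation layer
# ---------------------------------------------------------------------------

class SuccessorAgent:
    """Model object: an SR agent bound to a navigation task.

    ``fit`` runs the two-phase protocol (train on the task's target, then
    optionally probe a new target with the SR frozen) and returns an
    :class:`AgentResults`.
    """

    def __init__(self, actions: ActionModel, target: int, params: SRAgentParams, max_steps: int = 400):
        self.task = NavigationTask(actions, int(target), max_steps)
        self.params = params

    def fit(
        self,
        stop_rule: tuple = ("fixed_episodes", 400),
        seed: int | None = None,
        new_target: int | None = None,
        generalization_episodes: int = 100,
    ) -> "AgentResults":
        rng = np.random.default_rng(seed)
        state = SRAgentState.initial(self.task.n_states, self.params, rng)
        train_logs = train(state, self.task, self.params, rng, stop_rule)
        gen_logs: list[EpisodeLog] = []
        if new_target is not None:
            gen_logs = generalization_trial(
                state, self.task, new_target, self.params, rng, generalization_episodes
            )
        return AgentResults(self, state, train_logs, gen_logs)


class AgentResults:
    """Final agent state plus per-episode training and generalization logs."""

    def __init__(self, model, state, train_logs, gen_logs):
        self.model = model
        self.state = state
        self.train_logs = train_logs
        self.gen_logs = gen_logs

    @property
    def M(self) -> np.ndarray:
        return self.state.M

    def frame(self) -> pd.DataFrame:
        df_train = logs_to_frame(self.train_logs).assign(phase="train")
        if self.gen_logs:
            df_gen = logs_to_frame(self.gen_logs).assign(phase="generalize")
            return pd.concat([df_train, df_gen], ignore_index=True)
        return df_train

    def summary(self) -> str:
        p = self.model.params
        df = self.frame()
        lines = [
            "Successor-representation TD agent",
            "=================================",
            f"rule (alpha, beta)   ({p.alpha:.3g}, {p.beta:.3g})  variant={p.variant}",
            f"lr / gamma / temp    {p.lr} / {p.gamma} / {p.temperature}",
            f"training episodes    {len(self.train_logs)}",
            f"final-10 mean suboptimality  "
            f"{np.mean([lg.suboptimality for lg in self.train_logs[-10:]]):.2f}",
        ]
        if self.gen_logs:
            lines.append(
                f"generalization mean suboptimality ({len(self.gen_logs)} eps)  "
                f"{np.mean([lg.suboptimality for lg in self.gen_logs]):.2f}"
            )
        return "\n".join(lines)
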