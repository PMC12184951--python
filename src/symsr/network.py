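"""Two-layer rate network learning successor features with a local rule.

A recurrently connected population ``p1`` (CA3-like) drives a purely
feedforward population ``p2`` (CA1-like).  Both receive external input
``phi_i(S_t)`` tied to the current state of a Markov chain, relax quickly
to equilibrium, and adapt their weights with the temporally parametrized
rule

    dW = alpha (p_post(t+1) - W p_pre(t))   p_pre(t)^T
       + beta  (p_post(t)   - W p_pre(t+1)) p_pre(t+1)^T .

At convergence the per-state equilibrium activities encode
``(1 - gamma) x`` the successor representation of the blended chain
``P_{alpha,beta}``; ``alpha = beta`` extracts only the time-reversible part
of the dynamics.  The module provides the raw operations, exact
expected-update convergence losses, a parameter sweep, and a
statsmodels-flavoured :class:`TwoLayerSRNetwork` / :class:`TwoLayerSRResults`
pair wrapping them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .envs import FeatureMap, Trajectory, sample_trajectory
from .markov import (
    RuleParameters,
    TransitionModel,
    blend_transitions,
    stationary_distribution,
)

__all__ = [
    "NetworkParams",
    "NetworkState",
    "RunDiverged",
    "step_activity",
    "equilibrium_activity",
    "update_weights",
    "run_learning",
    "LearningRun",
    "convergence_loss",
    "convergence_loss_empirical",
    "closed_form_weights",
    "activity_maps",
    "rate_map",
    "parameter_sweep",
    "TwoLayerSRNetwork",
    "TwoLayerSRResults",
]

_DIVERGENCE_CAP = 1e6


class RunDiverged(RuntimeError):
    """Raised when activities or weights leave the finite/stable regime."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


@dataclass(frozen=True)
class NetworkParams:
    """Gains, rule parameters and step sizes of the two-layer network.

    ``eps_p`` (activity step) must exceed ``eps_w`` (weight step): learning
    assumes the population dynamics are fast relative to plasticity.
    """

    n1: int
    n2: int
    gamma1: float = 0.7
    gamma2: float = 0.7
    rule_r: RuleParameters = RuleParameters(1.0, 0.0)
    rule_f: RuleParameters = RuleParameters(1.0, 0.0)
    eps_p: float = 0.1
    eps_w: float = 0.01
    activation: str = "linear"
    w_init_scale: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma1 <= 1.0 and 0.0 <= self.gamma2 <= 1.0):
            raise ValueError("gains gamma1, gamma2 must lie in [0, 1]")
        if self.activation not in ("linear", "tanh", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        object.__setattr__(self, "rule_r", RuleParameters(*self.rule_r))
        object.__setattr__(self, "rule_f", RuleParameters(*self.rule_f))


@dataclass
class NetworkState:
    """Activities and weights of the network at one instant."""

    p1: np.ndarray
    p2: np.ndarray
    Wr: np.ndarray
    Wf: np.ndarray

    @classmethod
    def initial(
        cls, params: NetworkParams, rng: np.random.Generator | None = None, zeros: bool = False
    ) -> "NetworkState":
        """Fresh state: zero activities, small non-negative random weights."""
        n1, n2 = params.n1, params.n2
        if zeros or rng is None:
            Wr = np.zeros((n1, n1))
            Wf = np.zeros((n2, n1))
        else:
            Wr = rng.uniform(0.0, params.w_init_scale, size=(n1, n1))
            Wf = rng.uniform(0.0, params.w_init_scale, size=(n2, n1))
        return cls(np.zeros(n1), np.zeros(n2), Wr, Wf)


def _sigma(name: str) -> Callable[[np.ndarray], np.ndarray]:
    if name == "linear":
        return lambda x: x
    if name == "tanh":
        return np.tanh
    return lambda x: np.maximum(x, 0.0)


def step_activity(
    state: NetworkState, params: NetworkParams, phi1: np.ndarray, phi2: np.ndarray
) -> NetworkState:
    """One Euler step of the population dynamics (weights unchanged).

    ``p <- p + eps_p (-p + sigma(gamma W p + (1 - gamma) phi))`` for both
    layers; layer 2 is driven by layer 1's current activity.
    """
    sig = _sigma(params.activation)
    d1 = -state.p1 + sig(params.gamma1 * state.Wr @ state.p1 + (1 - params.gamma1) * phi1)
    d2 = -state.p2 + sig(params.gamma2 * state.Wf @ state.p1 + (1 - params.gamma2) * phi2)
    p1 = state.p1 + params.eps_p * d1
    p2 = state.p2 + params.eps_p * d2
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
        raise RunDiverged("non-finite activities: population dynamics diverged")
    return NetworkState(p1, p2, state.Wr, state.Wf)


def equilibrium_activity(
    params: NetworkParams,
    Wr: np.ndarray,
    Wf: np.ndarray,
    phi1: np.ndarray,
    phi2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium of the linear dynamics.

    ``p1 = (1 - gamma1)(I - gamma1 Wr)^{-1} phi1`` and
    ``p2 = gamma2 Wf p1 + (1 - gamma2) phi2``.  Requires a linear
    activation and spectral radius of ``gamma1 Wr`` below 1.
    """
    if params.activation != "linear":
        raise ValueError("closed-form equilibrium requires a linear activation")
    g1 = params.gamma1
    if g1 > 0:
        rho = np.max(np.abs(np.linalg.eigvals(Wr)))
        if g1 * rho >= 1.0:
            raise RunDiverged(
                f"equilibrium does not exist: spectral radius {rho:.3f} >= 1/gamma1"
            )
    p1 = (1 - g1) * np.linalg.solve(np.eye(params.n1) - g1 * Wr, phi1)
    p2 = params.gamma2 * Wf @ p1 + (1 - params.gamma2) * phi2
    return p1, p2


def update_weights(
    W: np.ndarray,
    p_pre_t: np.ndarray,
    p_pre_t1: np.ndarray,
    p_post_t: np.ndarray,
    p_post_t1: np.ndarray,
    rule: RuleParameters | tuple[float, float],
    eps_w: float,
) -> np.ndarray:
    """Apply one step of the parametrized local rule and return the new matrix."""
    alpha, beta = rule
    dW = alpha * np.outer(p_post_t1 - W @ p_pre_t, p_pre_t) + beta * np.outer(
        p_post_t - W @ p_pre_t1, p_pre_t1
    )
    return W + eps_w * dW


# ---------------------------------------------------------------------------
# equilibrium activity maps and exact convergence losses
# ---------------------------------------------------------------------------

def _equilibrium_maps(
    params: NetworkParams, Wr: np.ndarray, Wf: np.ndarray, Phi1: np.ndarray, Phi2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state equilibrium activities for all states at once (cells x states)."""
    g1, g2 = params.gamma1, params.gamma2
    if params.activation == "linear":
        A1 = (1 - g1) * np.linalg.solve(np.eye(params.n1) - g1 * Wr, Phi1)
        A2 = g2 * Wf @ A1 + (1 - g2) * Phi2
        return A1, A2
    sig = _sigma(params.activation)
    A1 = np.zeros_like(Phi1)
    for _ in range(500):
        nxt = sig(g1 * Wr @ A1 + (1 - g1) * Phi1)
        if np.max(np.abs(nxt - A1)) < 1e-12:
            A1 = nxt
            break
        A1 = nxt
    A2 = sig(g2 * Wf @ A1 + (1 - g2) * Phi2)
    return A1, A2


def activity_maps(
    params: NetworkParams,
    Wr: np.ndarray,
    Wf: np.ndarray,
    features1: FeatureMap,
    features2: FeatureMap,
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium activity of every cell in every state (cells x states)."""
    return _equilibrium_maps(params, Wr, Wf, features1.Phi, features2.Phi)


def convergence_loss(
    params: NetworkParams,
    Wr: np.ndarray,
    Wf: np.ndarray,
    tm: TransitionModel,
    features1: FeatureMap,
    features2: FeatureMap,
    pi: np.ndarray | None = None,
) -> tuple[float, float]:
    """Frobenius norms of the *exact* expected weight updates ``||E[dW]||``.

    The expectation runs over stationary state/successor pairs of the chain
    with activities at their equilibrium values; both norms vanish exactly
    at the learned fixed point.
    """
    if pi is None:
        pi = stationary_distribution(tm)
    C = pi[:, None] * tm.P  # joint stationary pair weights
    A1, A2 = _equilibrium_maps(params, Wr, Wf, features1.Phi, features2.Phi)
    A1pi = A1 * pi  # A1 @ diag(pi)
    G = A1pi @ A1.T  # E[p1 p1^T] = E[p1' p1'^T]
    ar, br = params.rule_r
    af, bf = params.rule_f
    E_r = ar * (A1 @ C.T @ A1.T - Wr @ G) + br * (A1 @ C @ A1.T - Wr @ G)
    E_f = af * (A2 @ C.T @ A1.T - Wf @ G) + bf * (A2 @ C @ A1.T - Wf @ G)
    return float(np.linalg.norm(E_r)), float(np.linalg.norm(E_f))


def convergence_loss_empirical(
    params: NetworkParams,
    Wr: np.ndarray,
    Wf: np.ndarray,
    trajectory: Trajectory,
    features1: FeatureMap,
    features2: FeatureMap,
) -> tuple[float, float]:
    """Trajectory-averaged estimator of the expected-update losses.

    Same quantity as :func:`convergence_loss` but with the expectation
    replaced by the empirical average over the observed transitions; for
    use when the generating chain is unknown.
    """
    states = np.asarray(trajectory.states)
    A1, A2 = _equilibrium_maps(params, Wr, Wf, features1.Phi, features2.Phi)
    s, s1 = states[:-1], states[1:]
    T = len(s)
    P1t, P1t1 = A1[:, s], A1[:, s1]
    P2t, P2t1 = A2[:, s], A2[:, s1]
    ar, br = params.rule_r
    af, bf = params.rule_f
    G_t = P1t @ P1t.T / T
    G_t1 = P1t1 @ P1t1.T / T
    E_r = ar * (P1t1 @ P1t.T / T - Wr @ G_t) + br * (P1t @ P1t1.T / T - Wr @ G_t1)
    E_f = af * (P2t1 @ P1t.T / T - Wf @ G_t) + bf * (P2t @ P1t1.T / T - Wf @ G_t1)
    return float(np.linalg.norm(E_r)), float(np.linalg.norm(E_f))


def closed_form_weights(
    tm: TransitionModel, params: NetworkParams
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point weights for one-hot features on the given chain.

    With identity feature matrices the recurrent weights converge to
    ``P_{alpha_r,beta_r}^T`` and the feedforward weights to
    ``(1-g2)/(1-g1) * P_f^T (I - g2 P_f^T)^{-1} (I - g1 P_r^T)`` with
    ``P_r``, ``P_f`` the blends under the respective rule parameters; at
    these weights the equilibrium activities equal ``(1 - gamma_i)`` times
    the corresponding successor-representation columns.
    """
    Pr = blend_transitions(tm, params.rule_r).P
    Pf = blend_transitions(tm, params.rule_f).P
    g1, g2 = params.gamma1, params.gamma2
    n = tm.n_states
    Wr = Pr.T.copy()
    inner = np.linalg.solve(np.eye(n) - g2 * Pf.T, np.eye(n) - g1 * Pr.T)
    Wf = (1 - g2) / (1 - g1) * Pf.T @ inner
    return Wr, Wf


# ---------------------------------------------------------------------------
# learning
# ---------------------------------------------------------------------------

@dataclass
class LearningRun:
    """Outcome of :func:`run_learning`: final state plus recorded traces."""

    state: NetworkState
    loss_trace: pd.DataFrame
    states: np.ndarray | None = None
    lap_ids: np.ndarray | None = None
    activity1: np.ndarray | None = None  # (T, n1) layer-1 activity per step
    activity2: np.ndarray | None = None


def _as_laps(
    source, T: int | None, seed: int | None
) -> tuple[list[np.ndarray], TransitionModel | None]:
    if isinstance(source, TransitionModel):
        if T is None:
            raise ValueError("T is required when learning directly from a chain")
        traj = sample_trajectory(source, T, seed=seed)
        return [traj.states], source
    if isinstance(source, Trajectory):
        return [np.asarray(source.states)], None
    return [np.asarray(lap) for lap in source], None


def run_learning(
    source,
    features1: FeatureMap,
    features2: FeatureMap,
    params: NetworkParams,
    T: int | None = None,
    seed: int | None = None,
    mode: str = "equilibrium",
    n_inner: int = 50,
    loss_tm: TransitionModel | None = None,
    loss_every: int | None = None,
    record_activities: bool = False,
    init_state: NetworkState | None = None,
) -> LearningRun:
    """Train the network along a state sequence.

    ``source`` may be a :class:`TransitionModel` (a trajectory of ``T``
    transitions is sampled with ``seed``), a :class:`Trajectory`, or a list
    of lap arrays (activities are reset between laps, mimicking a resting
    phase with no input; no weight updates occur during rest).

    ``mode='equilibrium'`` evaluates activities at their closed-form
    equilibria per state (linear activation), i.e. exact timescale
    separation; ``mode='integrate'`` runs ``n_inner`` Euler steps of the
    rate dynamics per visited state with step ``eps_p`` (which must then
    exceed ``eps_w``) and also supports tanh/relu activations.

    Raises :class:`RunDiverged` (with the offending step index) if weights
    or activities become non-finite or exceed the stability cap.
    """
    laps, chain = _as_laps(source, T, seed)
    if mode == "integrate" and params.eps_w > params.eps_p:
        raise ValueError("integration mode requires timescale separation eps_p >= eps_w")
    if loss_tm is None:
        loss_tm = chain
    rng = np.random.default_rng(seed)
    state = init_state or NetworkState.initial(params, rng)
    Wr, Wf = state.Wr.copy(), state.Wf.copy()
    Phi1, Phi2 = features1.Phi, features2.Phi
    g1, g2 = params.gamma1, params.gamma2
    sig = _sigma(params.activation)
    eye1 = np.eye(params.n1)
    ar, br = params.rule_r
    af, bf = params.rule_f

    losses: list[tuple[int, float, float]] = []
    total_steps = sum(len(lap) - 1 for lap in laps)
    act1 = np.empty((total_steps, params.n1)) if record_activities else None
    act2 = np.empty((total_steps, params.n2)) if record_activities else None
    visited = np.empty(total_steps, dtype=np.intp) if record_activities else None
    lap_ids = np.empty(total_steps, dtype=np.intp) if record_activities else None

    def record_loss(step: int) -> None:
        if loss_tm is not None:
            lr, lf = convergence_loss(params, Wr, Wf, loss_tm, features1, features2)
            losses.append((step, lr, lf))

    record_loss(0)
    step = 0
    for lap_no, lap in enumerate(laps):
        p1 = np.zeros(params.n1)
        p2 = np.zeros(params.n2)
        for s, s_next in zip(lap[:-1], lap[1:]):
            if mode == "equilibrium":
                B = (1 - g1) * Phi1[:, [s, s_next]]
                if params.activation == "linear":
                    try:
                        X = np.linalg.solve(eye1 - g1 * Wr, B)
                    except np.linalg.LinAlgError as err:
                        raise RunDiverged(f"singular equilibrium system: {err}", step)
                    p1_t, p1_t1 = X[:, 0], X[:, 1]
                    p2_t = g2 * Wf @ p1_t + (1 - g2) * Phi2[:, s]
                    p2_t1 = g2 * Wf @ p1_t1 + (1 - g2) * Phi2[:, s_next]
                else:
                    # nonlinear equilibria by fixed-point iteration
                    X = B.copy()
                    for _ in range(200):
                        nxt_X = sig(g1 * Wr @ X + B)
                        if np.max(np.abs(nxt_X - X)) < 1e-12:
                            X = nxt_X
                            break
                        X = nxt_X
                    p1_t, p1_t1 = X[:, 0], X[:, 1]
                    p2_t = sig(g2 * Wf @ p1_t + (1 - g2) * Phi2[:, s])
                    p2_t1 = sig(g2 * Wf @ p1_t1 + (1 - g2) * Phi2[:, s_next])
            elif mode == "integrate":
                phi1, phi2 = Phi1[:, s], Phi2[:, s]
                for _ in range(n_inner):
                    p1 = p1 + params.eps_p * (-p1 + sig(g1 * Wr @ p1 + (1 - g1) * phi1))
                    p2 = p2 + params.eps_p * (-p2 + sig(g2 * Wf @ p1 + (1 - g2) * phi2))
                p1_t, p2_t = p1.copy(), p2.copy()
                phi1, phi2 = Phi1[:, s_next], Phi2[:, s_next]
                for _ in range(n_inner):
                    p1 = p1 + params.eps_p * (-p1 + sig(g1 * Wr @ p1 + (1 - g1) * phi1))
                    p2 = p2 + params.eps_p * (-p2 + sig(g2 * Wf @ p1 + (1 - g2) * phi2))
                p1_t1, p2_t1 = p1.copy(), p2.copy()
            else:
                raise ValueError(f"unknown mode {mode!r}")

            if params.eps_w != 0.0:
                dWr = ar * np.outer(p1_t1 - Wr @ p1_t, p1_t) + br * np.outer(
                    p1_t - Wr @ p1_t1, p1_t1
                )
                dWf = af * np.outer(p2_t1 - Wf @ p1_t, p1_t) + bf * np.outer(
                    p2_t - Wf @ p1_t1, p1_t1
                )
                Wr += params.eps_w * dWr
                Wf += params.eps_w * dWf

            if record_activities:
                act1[step] = p1_t
                act2[step] = p2_t
                visited[step] = s
                lap_ids[step] = lap_no
            step += 1
            if not (np.all(np.isfinite(Wr)) and np.all(np.isfinite(Wf))) or max(
                np.max(np.abs(Wr)), np.max(np.abs(Wf))
            ) > _DIVERGENCE_CAP:
                raise RunDiverged("weights diverged", step)
            if loss_every and step % loss_every == 0:
                record_loss(step)
    if not losses or losses[-1][0] != step:
        record_loss(step)
    trace = pd.DataFrame(losses, columns=["step", "loss_r", "loss_f"])
    final = NetworkState(
        p1 if mode == "integrate" else np.zeros(params.n1),
        p2 if mode == "integrate" else np.zeros(params.n2),
        Wr,
        Wf,
    )
    return LearningRun(final, trace, visited, lap_ids, act1, act2)


def rate_map(activity: np.ndarray, states: np.ndarray, n_states: int) -> np.ndarray:
    """Mean activity of each cell per visited state (cells x states).

    States never visited are flagged with NaN columns.
    """
    activity = np.asarray(activity, dtype=float)
    states = np.asarray(states)
    if activity.shape[0] != len(states) or len(states) == 0:
        raise ValueError("activity trace and state sequence must align and be non-empty")
    sums = np.zeros((n_states, activity.shape[1]))
    counts = np.zeros(n_states)
    np.add.at(sums, states, activity)
    np.add.at(counts, states, 1.0)
    with np.errstate(invalid="ignore"):
        means = sums / counts[:, None]
    return means.T


def parameter_sweep(
    alpha_grid: Sequence[float],
    beta_grid: Sequence[float],
    tm: TransitionModel,
    features1: FeatureMap,
    features2: FeatureMap,
    base_params: NetworkParams,
    layer: str = "recurrent",
    fixed_other: tuple[float, float] | None = None,
    T: int = 1000,
    n_seeds: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Mean log10 final/initial convergence-loss ratio over an (alpha, beta) grid.

    One of the two rules is swept while the other layer's parameters stay
    fixed — by default (1, 0) when sweeping the recurrent rule and
    (1/2, 1/2) when sweeping the feedforward rule.  Each cell averages
    ``n_seeds`` random initializations trained for ``T`` transitions;
    divergent runs enter as +inf, a zero initial loss as NaN.
    """
    if layer not in ("recurrent", "feedforward"):
        raise ValueError("layer must be 'recurrent' or 'feedforward'")
    if fixed_other is None:
        fixed_other = (1.0, 0.0) if layer == "recurrent" else (0.5, 0.5)
    out = np.empty((len(alpha_grid), len(beta_grid)))
    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(len(alpha_grid) * len(beta_grid))
    for i, alpha in enumerate(alpha_grid):
        for j, beta in enumerate(beta_grid):
            rule = RuleParameters(alpha, beta)
            if layer == "recurrent":
                params = replace(base_params, rule_r=rule, rule_f=RuleParameters(*fixed_other))
            else:
                params = replace(base_params, rule_f=rule, rule_r=RuleParameters(*fixed_other))
            runs = cell_seeds[i * len(beta_grid) + j].spawn(n_seeds)
            ratios = []
            for ss in runs:
                run_seed = int(ss.generate_state(1)[0] % (2**31))
                try:
                    run = run_learning(tm, features1, features2, params, T=T, seed=run_seed)
                    trace = run.loss_trace
                    col = "loss_r" if layer == "recurrent" else "loss_f"
                    l0, l1 = trace[col].iloc[0], trace[col].iloc[-1]
                    ratios.append(np.log10(l1 / l0) if l0 > 0 else np.nan)
                except RunDiverged:
                    ratios.append(np.inf)
            out[i, j] = np.mean(ratios)
    return out


# ---------------------------------------------------------------------------
# model / results presentation layer
# ---------------------------------------------------------------------------

class TwoLayerSRNetwork:
    """Model object tying a chain (or lap schedule), features and parameters.

    Parameters
    ----------
    transitions
        A :class:`TransitionModel`, a :class:`Trajectory`, or a list of lap
        arrays (linear-track protocol).
    features1, features2
        Input feature maps of the recurrent and feedforward layer.  If
        ``features2`` is omitted the second layer sees the same features.
    params
        A :class:`NetworkParams`; layer sizes must match the feature maps.
    """

    def __init__(
        self,
        transitions,
        features1: FeatureMap,
        features2: FeatureMap | None = None,
        params: NetworkParams | None = None,
        **param_overrides,
    ):
        self.transitions = transitions
        self.features1 = features1
        self.features2 = features2 or features1
        if params is None:
            params = NetworkParams(
                n1=self.features1.n_cells, n2=self.features2.n_cells, **param_overrides
            )
        if params.n1 != self.features1.n_cells or params.n2 != self.features2.n_cells:
            raise ValueError("layer sizes must match the feature maps")
        self.params = params

    def fit(
        self,
        T: int | None = None,
        seed: int | None = None,
        mode: str = "equilibrium",
        loss_every: int | None = None,
        record_activities: bool = False,
    ) -> "TwoLayerSRResults":
        run = run_learning(
            self.transitions,
            self.features1,
            self.features2,
            self.params,
            T=T,
            seed=seed,
            mode=mode,
            loss_every=loss_every,
            record_activities=record_activities,
        )
        return TwoLayerSRResults(self, run)


class TwoLayerSRResults:
    """Fitted weights plus convergence diagnostics of a network run."""

    def __init__(self, model: TwoLayerSRNetwork, run: LearningRun):
        self.model = model
        self.run = run
        self.state = run.state
        self.loss_trace = run.loss_trace

    def activity_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-state equilibrium activities of both layers (cells x states)."""
        return activity_maps(
            self.model.params, self.state.Wr, self.state.Wf, self.model.features1, self.model.features2
        )

    def sr_estimate(self, layer: int = 1) -> np.ndarray:
        """Estimated successor representation encoded by a layer (states x cells).

        The per-state activity map divided by ``(1 - gamma)``; with one-hot
        inputs this is directly comparable to ``(I - gamma P_{a,b})^{-1}``.
        """
        A1, A2 = self.activity_maps()
        if layer == 1:
            return A1.T / (1 - self.model.params.gamma1)
        return A2.T / (1 - self.model.params.gamma2)

    def loss_ratio(self) -> tuple[float, float]:
        """log10 of final over initial expected-update loss, per layer."""
        t = self.loss_trace
        out = []
        for col in ("loss_r", "loss_f"):
            l0, l1 = t[col].iloc[0], t[col].iloc[-1]
            out.append(float(np.log10(l1 / l0)) if l0 > 0 else float("nan"))
        return out[0], out[1]

    def summary(self) -> str:
        p = self.model.params
        lr, lf = self.loss_trace[["loss_r", "loss_f"]].iloc[-1]
        rr, rf = self.loss_ratio()
        lines = [
            "Two-layer successor-feature network",
            "===================================",
            f"layer sizes            {p.n1} (recurrent), {p.n2} (feedforward)",
            f"gains gamma1/gamma2    {p.gamma1}/{p.gamma2}",
            f"recurrent rule (a, b)  ({p.rule_r.alpha}, {p.rule_r.beta})",
            f"feedforward rule       ({p.rule_f.alpha}, {p.rule_f.beta})",
            f"weight step eps_w      {p.eps_w}",
            f"final loss ||E[dW]||   {lr:.3e} (recurrent), {lf:.3e} (feedforward)",
            f"log10 loss ratio       {rr:+.2f} (recurrent), {rf:+.2f} (feedforward)",
        ]
        return "\n".join(lines)
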