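"""Experiment protocols: convergence, ring representations, place-field
centre-of-mass shift on a linear track, and navigation generalization.

Each ``experiment_*`` function is deterministic given its arguments and a
seed, returns tidy pandas objects, and is scaled by explicit arguments so
the same code runs both quick checks and full-size replications.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import layouts
from .agent import (
    NavigationTask,
    SRAgentParams,
    SRAgentState,
    generalization_trial,
    logs_to_frame,
    td_update,
    train,
)
from .envs import (
    circular_walk,
    graph_distances,
    grid_world,
    directed_tree_graph,
    linear_track,
    make_features,
)
from .markov import (
    RuleParameters,
    TransitionModel,
    blend_transitions,
    stationary_distribution,
    successor_matrix,
)
from .network import (
    NetworkParams,
    TwoLayerSRNetwork,
    parameter_sweep,
    rate_map,
)

__all__ = [
    "com",
    "COMShiftResult",
    "com_shift_analysis",
    "analytic_com_shift",
    "discrete_shift_comparison",
    "experiment_circular_sr",
    "experiment_convergence",
    "experiment_sweep",
    "experiment_linear_track",
    "experiment_generalization",
    "maze_generalization",
    "symmetrization_stability_check",
    "write_results",
]

RULES = {"asymmetric": RuleParameters(1.0, 0.0), "symmetric": RuleParameters(0.5, 0.5)}


def _child_seed(root: np.random.SeedSequence) -> int:
    return int(root.spawn(1)[0].generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# centre of mass
# ---------------------------------------------------------------------------

def com(rate_profile: np.ndarray, positions: np.ndarray) -> float:
    """Activity-weighted mean position of a non-negative rate profile."""
    p = np.asarray(rate_profile, dtype=float)
    x = np.asarray(positions, dtype=float)
    if p.shape != x.shape:
        raise ValueError("profile and positions must have the same shape")
    if np.any(p < 0):
        raise ValueError("rate profile must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total mass: centre of mass undefined")
    return float((x * p).sum() / total)


@dataclass
class COMShiftResult:
    """Per-cell COM shifts of one layer over laps."""

    shifts: pd.DataFrame  # cell, shift (last-five minus first-five mean COM)
    relative: pd.DataFrame  # lap, cell, com relative to the reference lap
    n_excluded: int

    @property
    def median_shift(self) -> float:
        return float(self.shifts["shift"].median())


def com_shift_analysis(
    rate_maps_per_lap: np.ndarray,
    positions: np.ndarray,
    n_first: int = 5,
    n_last: int = 5,
    ref_lap: int = 12,
) -> COMShiftResult:
    """Shift statistics from per-lap rate maps (laps x cells x positions).

    The overall shift per cell is the COM averaged over the last ``n_last``
    laps minus the COM averaged over the first ``n_first`` laps; the
    relative series subtracts the COM at the 1-based reference lap.  Cells
    with zero activity in any of the reference laps are excluded and
    counted.
    """
    maps = np.asarray(rate_maps_per_lap, dtype=float)
    if maps.ndim != 3:
        raise ValueError("expected an array of shape (laps, cells, positions)")
    n_laps, n_cells, _ = maps.shape
    if n_laps < max(n_first + n_last, ref_lap + 1):
        raise ValueError(
            f"need at least {max(n_first + n_last, ref_lap + 1)} laps, got {n_laps}"
        )
    coms = np.full((n_laps, n_cells), np.nan)
    for lap in range(n_laps):
        for cell in range(n_cells):
            profile = np.nan_to_num(maps[lap, cell], nan=0.0)
            if profile.sum() > 0:
                coms[lap, cell] = com(profile, positions)
    ref_rows = np.r_[0:n_first, n_laps - n_last : n_laps, ref_lap - 1]
    ok = ~np.isnan(coms[ref_rows]).any(axis=0)
    shifts = coms[n_laps - n_last :, ok].mean(axis=0) - coms[:n_first, ok].mean(axis=0)
    cells = np.flatnonzero(ok)
    shift_df = pd.DataFrame({"cell": cells, "shift": shifts})
    rel = pd.DataFrame(
        {
            "lap": np.repeat(np.arange(1, n_laps + 1), len(cells)),
            "cell": np.tile(cells, n_laps),
            "relative_com": (coms[:, ok] - coms[ref_lap - 1, ok]).ravel(),
        }
    )
    return COMShiftResult(shift_df, rel, int(n_cells - ok.sum()))


def analytic_com_shift(velocity: float, gamma_rate: float) -> float:
    """Predicted COM displacement ``-v / gamma`` of a successor feature.

    Under constant-velocity motion in continuous time, a cell whose tuning
    is replaced by its successor feature moves its centre of mass backward
    (opposite to travel) by velocity over the discount rate.
    """
    if gamma_rate <= 0:
        raise ValueError("gamma_rate must be positive")
    return -velocity / gamma_rate


def discrete_shift_comparison(
    gamma: float = 0.7,
    dt: float = 0.4,
    n_states: int = 50,
    track_cm: float = 300.0,
    p_right: float = 1.0,
    sigma: float = 4.0,
) -> tuple[float, float]:
    """COM shift of an exact successor feature on the discrete track vs -v/gamma.

    Builds the rightward walk, computes the successor feature of a Gaussian
    bump centred mid-track in closed form, and returns ``(simulated,
    predicted)`` shifts in cm.  The discrete per-step discount maps to a
    continuous rate via ``gamma_rate = -ln(gamma) / dt`` and the mean speed
    is ``p_right * (track_cm / n_states) / dt``.
    """
    tm, _ = linear_track(n_states, p_right, 1.0 - p_right)
    M = successor_matrix(tm, gamma).M
    dx = track_cm / n_states
    x = np.arange(n_states) * dx
    centre = n_states // 2
    phi = np.exp(-((np.arange(n_states) - centre) ** 2) / (2.0 * sigma))
    sf = M @ phi  # successor feature as a function of position
    shift = com(sf, x) - com(phi, x)
    v = p_right * dx / dt
    gamma_rate = -np.log(gamma) / dt
    return float(shift), analytic_com_shift(v, gamma_rate)


# ---------------------------------------------------------------------------
# ring representations (policy invariance of the symmetric rule)
# ---------------------------------------------------------------------------

@dataclass
class CircularSRResult:
    maps: dict  # (rule_name, policy_name) -> layer-1 SR estimate (states x cells)
    oracles: dict  # same keys -> closed-form SR of the blended chain
    report: pd.DataFrame


def _rel_diff(A: np.ndarray, B: np.ndarray) -> float:
    scale = max(np.max(np.abs(A)), np.max(np.abs(B)), 1e-300)
    return float(np.max(np.abs(A - B)) / scale)


def experiment_circular_sr(
    n_states: int = 30,
    gamma: float = 0.7,
    T: int = 100_000,
    eps_w: float = 0.02,
    seed: int = 0,
    policies: Sequence[str] = ("uniform", "cw", "acw"),
    rules: Sequence[str] = ("asymmetric", "symmetric"),
    bias: float = 0.8,
) -> CircularSRResult:
    """Learn ring representations under different walks and rules.

    Trains the two-layer network with one-hot inputs on uniform, clockwise-
    and anticlockwise-biased circular walks; reports the maximum relative
    difference between learned layer-1 maps across the two biased policies
    for each rule, and between each map and its closed-form blended-chain
    oracle.  The symmetric rule cannot distinguish the two biased walks.
    """
    rest = (1.0 - bias) / 2.0
    chains = {
        "uniform": circular_walk(n_states, 1 / 3, 1 / 3, 1 / 3),
        "cw": circular_walk(n_states, rest, bias, rest),
        "acw": circular_walk(n_states, rest, rest, bias),
    }
    feats = make_features("one_hot", n_states, n_states)
    root = np.random.SeedSequence(seed)
    maps: dict = {}
    oracles: dict = {}
    for rule_name in rules:
        for pol in policies:
            params = NetworkParams(
                n1=n_states, n2=n_states, gamma1=gamma, gamma2=gamma,
                rule_r=RULES[rule_name], rule_f=RULES[rule_name], eps_w=eps_w,
            )
            res = TwoLayerSRNetwork(chains[pol], feats, feats, params).fit(
                T=T, seed=_child_seed(root)
            )
            maps[(rule_name, pol)] = res.sr_estimate(layer=1)
            blended = blend_transitions(chains[pol], RULES[rule_name])
            oracles[(rule_name, pol)] = successor_matrix(blended, gamma).M
    rows = []
    for rule_name in rules:
        if "cw" in policies and "acw" in policies:
            rows.append(
                {
                    "comparison": f"{rule_name}: cw vs acw",
                    "max_rel_diff": _rel_diff(maps[(rule_name, "cw")], maps[(rule_name, "acw")]),
                }
            )
        for pol in policies:
            rows.append(
                {
                    "comparison": f"{rule_name}/{pol}: learned vs closed form",
                    "max_rel_diff": _rel_diff(maps[(rule_name, pol)], oracles[(rule_name, pol)]),
                }
            )
    return CircularSRResult(maps, oracles, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# convergence and parameter sweep
# ---------------------------------------------------------------------------

def experiment_convergence(
    n_states: int = 30,
    n_cells: int = 40,
    sigma: float = 0.1,
    gamma: float = 0.7,
    T: int = 100_000,
    n_repeats: int = 30,
    eps_w: float = 0.02,
    rules: Sequence[str] = ("asymmetric", "symmetric"),
    chain: str = "ring",
    seed: int = 0,
    loss_every: int = 1000,
) -> pd.DataFrame:
    """Convergence of both weight matrices on a ring (or random) walk.

    Uses i.i.d. Gaussian random features; returns a tidy frame of the
    expected-update losses along learning, one trace per repeat and rule.
    """
    root = np.random.SeedSequence(seed)
    frames = []
    for rule_name in rules:
        for rep in range(n_repeats):
            s_feat, s_run, s_chain = (
                _child_seed(root), _child_seed(root), _child_seed(root)
            )
            if chain == "ring":
                tm = circular_walk(n_states, 0.1, 0.8, 0.1)
            elif chain == "random":
                rng = np.random.default_rng(s_chain)
                P = rng.random((n_states, n_states)) + 1e-3
                tm = TransitionModel(P / P.sum(axis=1, keepdims=True))
            else:
                raise ValueError(f"unknown chain {chain!r}")
            feats = make_features("random", n_cells, n_states, sigma=sigma, seed=s_feat)
            params = NetworkParams(
                n1=n_cells, n2=n_cells, gamma1=gamma, gamma2=gamma,
                rule_r=RULES[rule_name], rule_f=RULES[rule_name], eps_w=eps_w,
            )
            res = TwoLayerSRNetwork(tm, feats, feats, params).fit(
                T=T, seed=s_run, loss_every=loss_every
            )
            df = res.loss_trace.assign(rule=rule_name, repeat=rep)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def experiment_sweep(
    alpha_grid: Sequence[float] = (-1.0, -0.5, 0.0, 0.5, 1.0),
    beta_grid: Sequence[float] = (-1.0, -0.5, 0.0, 0.5, 1.0),
    n_states: int = 10,
    n_cells: int = 20,
    sigma: float = 0.1,
    gamma: float = 0.7,
    T: int = 1000,
    n_seeds: int = 30,
    eps_w: float = 0.5,
    seed: int = 0,
    layers: Sequence[str] = ("recurrent", "feedforward"),
) -> dict[str, np.ndarray]:
    """Stability sweep: mean log10 loss ratio per (alpha, beta) cell and layer.

    The ring walk is clockwise-biased (stay .1, cw .8, acw .1) so that the
    forward and backward chains differ and the antidiagonal is a
    non-degenerate boundary; cells where the negative parameter dominates
    diverge (positive ratios), cells on the antidiagonal hover near 0.
    """
    tm = circular_walk(n_states, 0.1, 0.8, 0.1)
    root = np.random.SeedSequence(seed)
    feats = make_features("random", n_cells, n_states, sigma=sigma, seed=_child_seed(root))
    base = NetworkParams(n1=n_cells, n2=n_cells, gamma1=gamma, gamma2=gamma, eps_w=eps_w)
    out = {}
    for layer in layers:
        out[layer] = parameter_sweep(
            alpha_grid, beta_grid, tm, feats, feats, base,
            layer=layer, T=T, n_seeds=n_seeds, seed=_child_seed(root),
        )
    return out


# ---------------------------------------------------------------------------
# linear track
# ---------------------------------------------------------------------------

@dataclass
class LinearTrackResult:
    ca3: COMShiftResult
    ca1: COMShiftResult
    condition: str

    def summary(self) -> str:
        return (
            f"linear track ({self.condition} CA3 rule): median shift "
            f"CA3 {self.ca3.median_shift:+.2f} cm, CA1 {self.ca1.median_shift:+.2f} cm"
        )


def experiment_linear_track(
    recurrent_rule: str = "symmetric",
    n_states: int = 50,
    track_cm: float = 300.0,
    n_cells: int = 100,
    n_laps: int = 25,
    p_right: float = 0.9,
    gamma: float = 0.7,
    eps_w: float = 0.05,
    sigma: float = 4.0,
    seed: int = 0,
) -> LinearTrackResult:
    """Repeated laps on a linear track; per-lap COM shift of both layers.

    The feedforward (CA1) rule is always asymmetric (1, 0); the recurrent
    (CA3) rule is ``symmetric`` or ``asymmetric``.  Gaussian place-field
    inputs tile the track; activities reset in the rest phase between laps.
    """
    if n_laps < 2:
        raise ValueError("shift analysis needs more than one lap")
    _, sampler = linear_track(n_states, p_right, 1.0 - p_right)
    root = np.random.SeedSequence(seed)
    laps = sampler.sample(n_laps, seed=_child_seed(root))
    feats = make_features("gaussian", n_cells, n_states, sigma=sigma)
    params = NetworkParams(
        n1=n_cells, n2=n_cells, gamma1=gamma, gamma2=gamma,
        rule_r=RULES[recurrent_rule], rule_f=RULES["asymmetric"], eps_w=eps_w,
    )
    res = TwoLayerSRNetwork(laps, feats, feats, params).fit(
        seed=_child_seed(root), record_activities=True
    )
    run = res.run
    dx = track_cm / n_states
    positions = np.arange(n_states) * dx
    maps1 = np.empty((n_laps, n_cells, n_states))
    maps2 = np.empty((n_laps, n_cells, n_states))
    # firing rates are non-negative: rectify the linear model's activities
    # before treating them as place-field profiles
    a1 = np.maximum(run.activity1, 0.0)
    a2 = np.maximum(run.activity2, 0.0)
    for lap in range(n_laps):
        sel = run.lap_ids == lap
        maps1[lap] = rate_map(a1[sel], run.states[sel], n_states)
        maps2[lap] = rate_map(a2[sel], run.states[sel], n_states)
    ca3 = com_shift_analysis(maps1, positions)
    ca1 = com_shift_analysis(maps2, positions)
    return LinearTrackResult(ca3, ca1, recurrent_rule)


# ---------------------------------------------------------------------------
# navigation generalization
# ---------------------------------------------------------------------------

AGENT_RULES = {
    "classical": dict(alpha=1.0, beta=0.0),
    "symmetric": dict(alpha=0.5, beta=0.5),
}


def _environment(env: str):
    if env == "directed_graph":
        space, actions = directed_tree_graph()
    elif env in layouts.SYMMETRIC_FIXTURES:
        space, actions = grid_world(layouts.SYMMETRIC_FIXTURES[env])
    elif env in layouts.MAZE_FIXTURES:
        space, actions = grid_world(layouts.MAZE_FIXTURES[env])
    else:
        space, actions = grid_world(env)  # treat as a literal layout
    return space, actions


def _agent_params(agent: str, lr: float, gamma: float, temperature: float, **kw) -> SRAgentParams:
    if agent.startswith("interpolated:"):
        return SRAgentParams.interpolated(
            float(agent.split(":", 1)[1]), lr=lr, gamma=gamma, temperature=temperature, **kw
        )
    base = AGENT_RULES[agent.split(":")[0].replace("noisy-", "").replace("hetero-", "")]
    variant = "fixed"
    extra = {}
    if agent.startswith("noisy-"):
        variant = "noisy"
    elif agent.startswith("hetero-"):
        variant = "heterogeneous"
        extra["hetero_means"] = (base["alpha"], base["beta"])
    return SRAgentParams(
        **base, lr=lr, gamma=gamma, temperature=temperature, variant=variant, **extra, **kw
    )


def experiment_generalization(
    env: str = "empty_room",
    agents: Sequence[str] = ("classical", "symmetric"),
    n_reps: int = 30,
    episodes: int = 400,
    gen_episodes: int = 100,
    max_steps: int = 400,
    lr: float = 0.1,
    gamma: float = 0.7,
    temperature: float = 0.01,
    stop_rule: str = "fixed",
    seed: int = 0,
    same_data: bool = False,
) -> pd.DataFrame:
    """Two-phase navigation protocol on a grid world or the directed graph.

    Phase 1 trains each agent on a randomly drawn target (fixed episode
    budget or the accuracy criterion); phase 2 freezes the SR, draws a new
    target and relearns only the reward vector.  Target pairs are drawn
    identically across agents within a repetition so comparisons are
    paired.  ``same_data=True`` trains the non-classical agents' SR on the
    exact transition stream sampled by the classical agent.

    Returns a tidy frame (agent, rep, phase, episode, steps,
    suboptimality, entropy, terminal).
    """
    space, actions = _environment(env)
    n = actions.n_states
    D = graph_distances(actions)
    reachable = [s for s in range(n) if np.isfinite(D[:, s]).sum() > 1]
    root = np.random.SeedSequence(seed)
    rule = (
        ("fixed_episodes", episodes) if stop_rule == "fixed" else ("accuracy", 8, 2.0)
    )
    frames = []
    for rep in range(n_reps):
        rep_rng = np.random.default_rng(_child_seed(root))
        target = int(reachable[rep_rng.integers(len(reachable))])
        others = [s for s in reachable if s != target]
        new_target = int(others[rep_rng.integers(len(others))])
        run_seed = _child_seed(root)
        if same_data:
            frames.extend(
                _same_data_rep(
                    actions, target, new_target, agents, rule, gen_episodes,
                    max_steps, lr, gamma, temperature, run_seed, rep,
                )
            )
            continue
        for agent in agents:
            params = _agent_params(agent, lr, gamma, temperature)
            rng = np.random.default_rng(run_seed)
            task = NavigationTask(actions, target, max_steps)
            state = SRAgentState.initial(n, params, rng)
            logs = train(state, task, params, rng, rule)
            gen = generalization_trial(state, task, new_target, params, rng, gen_episodes)
            df = pd.concat(
                [
                    logs_to_frame(logs).assign(phase="train"),
                    logs_to_frame(gen).assign(phase="generalize"),
                ],
                ignore_index=True,
            ).assign(agent=agent, rep=rep)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _same_data_rep(
    actions, target, new_target, agents, rule, gen_episodes, max_steps,
    lr, gamma, temperature, run_seed, rep,
):
    """Train all SRs on the classical agent's transition stream (shared data)."""
    params_c = _agent_params("classical", lr, gamma, temperature)
    rng = np.random.default_rng(run_seed)
    task = NavigationTask(actions, target, max_steps)
    n = actions.n_states
    state_c = SRAgentState.initial(n, params_c, rng)
    shadows = {
        a: (SRAgentState.initial(n, _agent_params(a, lr, gamma, temperature), rng),
            _agent_params(a, lr, gamma, temperature))
        for a in agents
        if a != "classical"
    }
    # manual training loop so every transition can be replayed into the shadows
    logs = []
    n_episodes = rule[1] if rule[0] == "fixed_episodes" else 400
    from .agent import policy_entropy, q_values, select_action, update_reward

    starts = task.start_states()
    for ep in range(int(n_episodes)):
        s = int(starts[rng.integers(len(starts))])
        start_state, steps, terminal = s, 0, False
        while steps < max_steps:
            a = select_action(q_values(state_c, s, actions), temperature, rng)
            s_next = int(actions.next_state[s, a])
            r = 1.0 if s_next == task.target else 0.0
            td_update(state_c, s, s_next, params_c)
            update_reward(state_c, s_next, r, params_c.reward_lr)
            for shadow, p_s in shadows.values():
                td_update(shadow, s, s_next, p_s)
                update_reward(shadow, s_next, r, p_s.reward_lr)
            s = s_next
            steps += 1
            if s == task.target:
                terminal = True
                break
        logs.append(
            dict(
                episode=ep, steps=steps, start=start_state, target=target,
                suboptimality=steps - task.optimal_steps(start_state),
                entropy=policy_entropy(state_c, actions, temperature),
                terminal=terminal,
            )
        )
    frames = [pd.DataFrame(logs).assign(phase="train", agent="classical", rep=rep)]
    all_states = {"classical": (state_c, params_c)}
    all_states.update({a: (st, p) for a, (st, p) in shadows.items()})
    for agent, (st, p) in all_states.items():
        gen = generalization_trial(st, task, new_target, p, rng, gen_episodes)
        frames.append(logs_to_frame(gen).assign(phase="generalize", agent=agent, rep=rep))
    return frames


def maze_generalization(
    train_env: str = "maze_train",
    test_envs: Sequence[str] = ("maze_blocked_a", "maze_blocked_b", "maze_blocked_c"),
    agents: Sequence[str] = ("classical", "symmetric"),
    n_reps: int = 10,
    episodes: int = 400,
    gen_episodes: int = 50,
    max_steps: int = 400,
    lr: float = 0.999,
    gamma: float = 0.9,
    temperature: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Maze protocol: train in the open maze, generalize in blocked variants.

    The test variants block previously open corridor cells; the trained SR
    is restricted to the surviving states (rows/columns dropped) and only
    the reward vector is relearned toward a new target.
    """
    space_tr, actions_tr = _environment(train_env)
    coords_tr = [tuple(map(int, c)) for c in space_tr.coords]
    root = np.random.SeedSequence(seed)
    frames = []
    for rep in range(n_reps):
        rep_rng = np.random.default_rng(_child_seed(root))
        target = int(rep_rng.integers(actions_tr.n_states))
        run_seed = _child_seed(root)
        test_env = test_envs[rep % len(test_envs)]
        space_te, actions_te = _environment(test_env)
        coords_te = [tuple(map(int, c)) for c in space_te.coords]
        keep = np.array([coords_tr.index(c) for c in coords_te])
        for agent in agents:
            params = _agent_params(agent, lr, gamma, temperature)
            rng = np.random.default_rng(run_seed)
            task = NavigationTask(actions_tr, target, max_steps)
            state = SRAgentState.initial(actions_tr.n_states, params, rng)
            logs = train(state, task, params, rng, ("fixed_episodes", episodes))
            restricted = SRAgentState(
                state.M[np.ix_(keep, keep)].copy(), np.zeros(len(keep))
            )
            test_task = NavigationTask(actions_te, 0, max_steps)
            new_target = int(rng.integers(actions_te.n_states))
            gen = generalization_trial(
                restricted, test_task, new_target, params, rng, gen_episodes
            )
            df = pd.concat(
                [
                    logs_to_frame(logs).assign(phase="train", env=train_env),
                    logs_to_frame(gen).assign(phase="generalize", env=test_env),
                ],
                ignore_index=True,
            ).assign(agent=agent, rep=rep)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def symmetrization_stability_check(
    actions, gamma: float = 0.7, targets: Sequence[int] | None = None
) -> int:
    """Count greedy actions that leave a shortest path after symmetrization.

    For every target, an optimal deterministic policy (each state steps to
    a BFS parent) is symmetrized the way the symmetric learning rule
    symmetrizes experience: the stationary edge flows of the episodic
    chain (the policy plus a uniform restart at the target) are summed
    with their reverses and renormalized, *excluding* the restart jumps —
    episode boundaries are not experienced transitions.  The value
    function of the symmetrized chain's successor representation is
    computed in closed form and every greedy action (relative tie
    tolerance, since values decay like gamma^d) is checked to strictly
    decrease the distance to the target.  Returns the number of
    violations; 0 means the optimal policy is stable under symmetrization.
    """
    n = actions.n_states
    D = graph_distances(actions)
    violations = 0
    eye = np.eye(n)
    for t in range(n) if targets is None else targets:
        d = D[:, t]
        if not np.all(np.isfinite(d)):
            continue
        P = np.zeros((n, n))
        for s in range(n):
            if s == t:
                P[s] = 1.0 / (n - 1)
                P[s, s] = 0.0
            else:
                nxt = actions.next_state[s]
                best = nxt[np.argmin(d[nxt])]
                P[s, int(best)] = 1.0
        pi = stationary_distribution(TransitionModel(P))
        flows = pi[:, None] * P
        flows[t, :] = 0.0  # restart jumps are not experienced transitions
        sym = flows + flows.T
        P_sym = sym / sym.sum(axis=1, keepdims=True)
        v = np.linalg.inv(eye - gamma * P_sym)[:, t]
        for s in range(n):
            if s == t:
                continue
            nxt = actions.next_state[s]
            q = v[nxt]
            greedy = nxt[q >= q.max() * (1.0 - 1e-6)]
            if np.any(d[greedy] != d[s] - 1):
                violations += 1
    return violations


# ---------------------------------------------------------------------------
# results on disk
# ---------------------------------------------------------------------------

def write_results(
    outdir, name: str, frames: dict[str, pd.DataFrame], config: dict, seed: int
) -> Path:
    """Write tidy CSVs plus a manifest (config hash, seed, version)."""
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for key, df in frames.items():
        df.to_csv(out / f"{name}_{key}.csv", index=False)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "experiment": name,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "symsr_version": __version__,
    }
    with open(out / f"{name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
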