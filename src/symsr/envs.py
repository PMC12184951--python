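"""State spaces, policies, feature maps and trajectory sampling.

Everything the experiments consume is generated here: ring and linear-track
random walks, grid worlds parsed from ASCII layouts, the directed
tree-with-return graph, uniform policies over deterministic action models,
one-hot / Gaussian-bump / frozen-random feature maps, and seeded
Markov-chain trajectory samplers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .markov import TransitionModel

__all__ = [
    "StateSpace",
    "ActionModel",
    "FeatureMap",
    "Trajectory",
    "LapSampler",
    "circular_walk",
    "linear_track",
    "grid_world",
    "directed_tree_graph",
    "uniform_policy_transitions",
    "make_features",
    "sample_trajectory",
    "graph_distances",
]


@dataclass(frozen=True)
class StateSpace:
    """A finite state set with adjacency structure and optional coordinates."""

    kind: str  # ring | line | grid | directed_graph
    n_states: int
    adjacency: np.ndarray  # boolean n x n, directed
    coords: np.ndarray | None = None  # (n, d) spatial coordinates

    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.adjacency, self.adjacency.T))


@dataclass(frozen=True)
class ActionModel:
    """Deterministic action-conditioned transitions ``next_state(s, a)``.

    ``next_state`` is total on S x A; moves into walls or absent edges map
    to staying in place when ``blocked_stay`` is set.
    """

    actions: tuple[str, ...]
    next_state: np.ndarray  # int array (n_states, n_actions)
    blocked_stay: bool = True

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    @property
    def n_states(self) -> int:
        return self.next_state.shape[0]


@dataclass(frozen=True)
class FeatureMap:
    """Feature matrix Phi with one column per state (m cells x n states)."""

    Phi: np.ndarray
    kind: str
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.Phi.shape[0]

    @property
    def n_states(self) -> int:
        return self.Phi.shape[1]


@dataclass(frozen=True)
class Trajectory:
    """An ordered state sequence, optionally with actions and lap boundaries."""

    states: np.ndarray
    actions: np.ndarray | None = None
    lap_bounds: tuple[tuple[int, int], ...] | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# ring and track walks
# ---------------------------------------------------------------------------

def circular_walk(
    n_states: int, p_stay: float, p_cw: float, p_acw: float
) -> TransitionModel:
    """Ring walk with per-step action probabilities stay / clockwise / anticlockwise."""
    probs = np.array([p_stay, p_cw, p_acw], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-10:
        raise ValueError("p_stay, p_cw, p_acw must be non-negative and sum to 1")
    if n_states < 2:
        raise ValueError("a ring needs at least 2 states")
    P = np.zeros((n_states, n_states))
    idx = np.arange(n_states)
    P[idx, idx] += p_stay
    P[idx, (idx + 1) % n_states] += p_cw
    P[idx, (idx - 1) % n_states] += p_acw
    return TransitionModel(P)


class LapSampler:
    """Samples start-to-end laps of a rightward-biased linear-track walk.

    Each lap begins at state 0 and ends on first arrival at state ``n - 1``.
    Between laps the protocol inserts a short resting phase of
    ``rest_steps`` steps with no external input (the network resets its
    activities there; no weight updates are applied during rest).
    """

    def __init__(self, n_states: int, p_right: float, rest_steps: int = 10):
        self.n_states = n_states
        self.p_right = p_right
        self.rest_steps = rest_steps

    def sample_lap(self, rng: np.random.Generator) -> np.ndarray:
        states = [0]
        s = 0
        while s < self.n_states - 1:
            if self.p_right >= 1.0 or rng.random() < self.p_right:
                s += 1
            states.append(s)
        return np.asarray(states, dtype=np.intp)

    def sample(self, n_laps: int, seed: int | None = None) -> list[np.ndarray]:
        rng = np.random.default_rng(seed)
        return [self.sample_lap(rng) for _ in range(n_laps)]


def linear_track(
    n_states: int = 50, p_right: float = 0.9, p_stay: float = 0.1, rest_steps: int = 10
) -> tuple[TransitionModel, LapSampler]:
    """Rightward-biased walk on a line; returns the chain and a lap sampler.

    The walk either steps right (``p_right``) or stays (``p_stay``); the
    terminal state is modelled as absorbing in the transition matrix (laps
    are handled by the sampler, which resets to state 0).
    """
    if p_right < 0 or p_stay < 0 or abs(p_right + p_stay - 1.0) > 1e-10:
        raise ValueError("p_right + p_stay must equal 1 with both non-negative")
    if n_states < 2:
        raise ValueError("a track needs at least 2 states")
    P = np.zeros((n_states, n_states))
    idx = np.arange(n_states - 1)
    P[idx, idx] = p_stay
    P[idx, idx + 1] = p_right
    P[n_states - 1, n_states - 1] = 1.0
    return TransitionModel(P), LapSampler(n_states, p_right, rest_steps)


# ---------------------------------------------------------------------------
# grid worlds
# ---------------------------------------------------------------------------

_GRID_ACTIONS = ("up", "down", "left", "right")
_GRID_MOVES = {"up": (-1, 0), "down": (1, 0), "left": (0, -1), "right": (0, 1)}


def grid_world(layout_text: str) -> tuple[StateSpace, ActionModel]:
    """Parse an ASCII layout (``#`` wall, ``.`` free) into states and actions.

    Free cells become states in reading order; the four moves are
    deterministic, and a move into a wall or the border stays in place.
    """
    lines = [ln for ln in layout_text.strip("\n").splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty layout")
    width = len(lines[0])
    if any(len(ln) != width for ln in lines):
        raise ValueError("layout must be rectangular")
    bad = set("".join(lines)) - {"#", "."}
    if bad:
        raise ValueError(f"layout may only contain '#' and '.', found {sorted(bad)!r}")
    cell_id: dict[tuple[int, int], int] = {}
    coords = []
    for r, ln in enumerate(lines):
        for c, ch in enumerate(ln):
            if ch == ".":
                cell_id[(r, c)] = len(coords)
                coords.append((r, c))
    n = len(coords)
    if n == 0:
        raise ValueError("layout has no free cells")
    next_state = np.empty((n, 4), dtype=np.intp)
    for (r, c), s in cell_id.items():
        for a, name in enumerate(_GRID_ACTIONS):
            dr, dc = _GRID_MOVES[name]
            next_state[s, a] = cell_id.get((r + dr, c + dc), s)
    adjacency = np.zeros((n, n), dtype=bool)
    for s in range(n):
        for t in next_state[s]:
            if t != s:
                adjacency[s, t] = True
    space = StateSpace("grid", n, adjacency, coords=np.asarray(coords, dtype=float))
    return space, ActionModel(_GRID_ACTIONS, next_state)


def directed_tree_graph(
    levels_spec: Sequence[int] = (1, 4, 12), back_edges_to_root: bool = True
) -> tuple[StateSpace, ActionModel]:
    """Tree with downward edges plus directed leaf-to-root return edges.

    The default (1, 4, 12) split gives the 17-node graph: a root, 4
    mid-level nodes and 12 leaves (3 per mid-level node), with one directed
    edge from each leaf back to the root.  Travel time is asymmetric:
    d(leaf, root) = 1 while d(root, leaf) = 2.
    """
    levels = [int(x) for x in levels_spec]
    if len(levels) < 2 or any(x < 1 for x in levels):
        raise ValueError("levels_spec must give at least 2 positive levels")
    offsets = np.concatenate([[0], np.cumsum(levels)])
    n = int(offsets[-1])
    children: list[list[int]] = [[] for _ in range(n)]
    for lvl in range(len(levels) - 1):
        parents = range(offsets[lvl], offsets[lvl + 1])
        kids = list(range(offsets[lvl + 1], offsets[lvl + 2]))
        # distribute children evenly over parents, in order
        per = len(kids) // levels[lvl]
        extra = len(kids) % levels[lvl]
        k = 0
        for i, p in enumerate(parents):
            take = per + (1 if i < extra else 0)
            children[p] = kids[k : k + take]
            k += take
    leaves = range(offsets[-2], offsets[-1])
    if back_edges_to_root:
        for leaf in leaves:
            children[leaf] = [0]
    max_out = max(1, max(len(c) for c in children))
    next_state = np.empty((n, max_out), dtype=np.intp)
    for s in range(n):
        for a in range(max_out):
            next_state[s, a] = children[s][a] if a < len(children[s]) else s
    adjacency = np.zeros((n, n), dtype=bool)
    for s in range(n):
        for t in children[s]:
            adjacency[s, t] = True
    space = StateSpace("directed_graph", n, adjacency)
    actions = tuple(f"edge{i}" for i in range(max_out))
    return space, ActionModel(actions, next_state)


def uniform_policy_transitions(
    space: StateSpace, actions: ActionModel
) -> TransitionModel:
    """Transition matrix of the policy choosing every action with equal probability."""
    n = actions.n_states
    P = np.zeros((n, n))
    w = 1.0 / actions.n_actions
    for a in range(actions.n_actions):
        np.add.at(P, (np.arange(n), actions.next_state[:, a]), w)
    return TransitionModel(P)


def graph_distances(actions: ActionModel) -> np.ndarray:
    """All-pairs BFS path lengths over the directed action graph (inf if unreachable)."""
    n = actions.n_states
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for s in range(n):
        for t in set(actions.next_state[s]) - {s}:
            G.add_edge(s, int(t))
    D = np.full((n, n), np.inf)
    for s, dists in nx.all_pairs_shortest_path_length(G):
        for t, d in dists.items():
            D[s, t] = d
    return D


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _state_distances(space: StateSpace | int, centres: np.ndarray) -> np.ndarray:
    """Distance from every state to every centre, respecting ring wrap-around."""
    if isinstance(space, int):
        pos = np.arange(space, dtype=float)[:, None]
        kind = "line"
    elif space.coords is not None:
        pos = np.asarray(space.coords, dtype=float)
        kind = space.kind
    else:
        pos = np.arange(space.n_states, dtype=float)[:, None]
        kind = space.kind
    if pos.ndim == 1:
        pos = pos[:, None]
    diff = pos[None, :, :] - pos[centres][:, None, :]
    if kind == "ring":
        n = pos.shape[0]
        diff = (diff + n / 2) % n - n / 2
    return np.sqrt((diff ** 2).sum(axis=-1))


def make_features(
    kind: str,
    n_cells: int,
    space: StateSpace | int,
    sigma: float = 0.1,
    seed: int | None = None,
) -> FeatureMap:
    """Build a frozen feature map of the given kind.

    Parameters
    ----------
    kind
        ``one_hot`` (requires ``n_cells == n_states``), ``gaussian``
        (bumps ``exp(-d^2 / (2 sigma))`` centred on evenly spaced states,
        ``sigma`` in squared state units), or ``random`` (i.i.d. draws from
        ``N(0, sigma^2)``, ``sigma`` the standard deviation, default 0.1).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    n_states = space if isinstance(space, int) else space.n_states
    if kind == "one_hot":
        if n_cells != n_states:
            raise ValueError("one-hot features require n_cells == n_states")
        return FeatureMap(np.eye(n_states), kind)
    if kind == "gaussian":
        centres = np.round(np.linspace(0, n_states - 1, n_cells)).astype(np.intp)
        d = _state_distances(space, centres)  # (n_cells, n_states)
        return FeatureMap(np.exp(-(d ** 2) / (2.0 * sigma)), kind)
    if kind == "random":
        rng = np.random.default_rng(seed)
        return FeatureMap(rng.normal(0.0, sigma, size=(n_cells, n_states)), kind, seed)
    raise ValueError(f"unknown feature kind {kind!r}")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def sample_trajectory(
    tm: TransitionModel, T: int, seed: int | None = None, init: int | None = None
) -> Trajectory:
    """Sample ``T`` transitions of the chain (a sequence of ``T + 1`` states)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    n = tm.n_states
    rng = np.random.default_rng(seed)
    if init is None:
        s = int(rng.integers(n))
    else:
        if not 0 <= init < n:
            raise ValueError(f"init state {init} out of range [0, {n})")
        s = int(init)
    cum = np.cumsum(tm.P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(T)
    states = np.empty(T + 1, dtype=np.intp)
    states[0] = s
    for t in range(T):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        states[t + 1] = s
    return Trajectory(states=states, seed=seed)
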