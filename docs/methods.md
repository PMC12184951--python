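# Methods

## The model in brief

`symsr` studies what a predictive map of a state space looks like when the
learning rule that builds it is, or is not, sensitive to the arrow of time.
The central object is the successor representation (SR) of a Markov chain
with transition matrix `P` and discount `γ ∈ [0, 1)`,

    M = (I − γP)⁻¹ = Σ_k γᵏ Pᵏ ,

whose entry `M[s, s′]` is the discounted expected number of future visits
to `s′` from `s`.  Every learner in the package is characterised by a pair
of weights `(α, β)`: `α` weighs prediction of the *next* observation from
the current one, `β` weighs prediction of the *current* observation from
the next.  At stationarity, any such learner converges to the SR not of the
experienced chain but of the blend

    P_{α,β} = α/(α+β) · P + β/(α+β) · P_back ,    P_back = Π⁻¹ Pᵀ Π ,

where `Π = diag(π)` holds the stationary distribution.  `(1, 0)` recovers
the classical SR, `(0, 1)` the predecessor representation, and `α = β`
yields the symmetrized chain `(P + P_back)/2`, which always satisfies
detailed balance: a time-symmetric rule can only retain the reversible part
of the dynamics.  `α + β = 0` is a true boundary — the blend is undefined
and learning does not converge there.

Three learners implement this picture at different levels:

1. **Exact linear algebra** (`symsr.markov`): stationary distributions by a
   direct linear solve (tolerance 1e-12, never power iteration), backward
   and blended chains, closed-form SRs, detailed-balance tests, and the
   geometric closed form of the SR of a shortest-path policy.  These are
   the oracles everything else is tested against.
2. **A two-layer rate network** (`symsr.network`): a recurrent population
   `p1` (CA3-like) drives a feedforward population `p2` (CA1-like), each
   relaxing to equilibrium under external input `φ_i(S_t)` with gains
   `γ1, γ2` — the same numbers reappear as the SR discounts.  Both weight
   matrices follow the local rule
   `ΔW = α(p⁺_{t+1} − W p⁻_t) p⁻ᵀ_t + β(p⁺_t − W p⁻_{t+1}) p⁻ᵀ_{t+1}`,
   a Hebbian product with subtractive normalization of total input.  With
   one-hot inputs the converged per-state activities are exactly
   `(1 − γ_i) ×` the columns of the blended SR; the fixed-point weights are
   `W_r* = P_{α_r,β_r}ᵀ` and a matching closed form for `W_f*`
   (`closed_form_weights`), which the tests verify to machine precision
   through the exact expected-update losses below.
3. **A tabular TD agent** (`symsr.agent`): the generalized update changes
   rows `s` and `s′` of the estimate `M` with weights `α` and `β`; under a
   frozen policy its expected update vanishes exactly at the blended SR
   (`E[ΔM] = (α+β) Π (I + γ P_{α,β} M − M)`).  Variants add per-step
   Gaussian noise to `(α, β)` or a frozen per-state-pair field of
   `|N(μ, σ)|` parameters.

## Convergence diagnostics

The loss attached to every network run is the Frobenius norm of the *exact*
expected weight update, `ℒ_W = ‖E[ΔW]‖`, with the expectation taken over
stationary state/successor pairs and activities at equilibrium.  Because
both `π` and `P` are known in every experiment, the expectation is computed
in closed form (the empirical per-trajectory estimator is also provided and
agrees to a few percent at 2·10⁵ transitions).  The parameter sweep reports
`log₁₀(ℒ_final / ℒ_initial)` per `(α, β)` cell: negative means movement
toward the fixed point, values near 0 on the antidiagonal mark the
undefined boundary, and cells where the negative parameter dominates in
absolute value diverge.  The `(0, 0)` cell is skipped in antidiagonal
averages — the null rule makes no updates, so its ratio is 0/0.

## Parameters, defaults, and where they come from

Protocol constants stated by the study conditions and kept at those values:
`γ = 0.7` throughout (0.9 in the maze variant), rings of 30 states for the
fixed-point runs and 10 states / 20 cells / 1000 iterations / 30
initializations per cell for the sweep, random features i.i.d.
`N(0, 0.1²)`, 10⁵ observed transitions for convergence runs, a 300 cm
linear track cut into 50 states with `p_right = 0.9` and `dt = 0.4 s`
(6 cm per step ≈ 15 cm/s ignoring the stay probability; 13.5 cm/s with
it), 25 laps, 100 cells per layer, navigation episodes capped at 400 steps
with 400 training episodes on grids and 50 on the 17-node graph, learning
rate 0.1, and 30 repetitions for distribution-level comparisons (scaled
from 200; full scale is a config change).

Values the protocol leaves open, chosen once and frozen:

* **Weight step `ε_W`** — 0.5 for the 1000-iteration sweep (with feature
  scale σ = 0.1 the effective rate is ~`(1−γ)²σ²` smaller than `ε_W`),
  0.02 for the 10⁵-step one-hot ring runs, 0.05 for the linear track.
  Chosen for stable, visible convergence at the stated run lengths.
* **Weight initialization** — i.i.d. uniform on [0, 0.01] (small
  non-negative), seeded; zeros available.
* **Activity handling** — closed-form equilibria per visited state
  (exact timescale separation) by default; an Euler-integration mode with
  `ε_p = 0.1` and 50 inner steps per state cross-checks it and supports
  tanh/relu activations (for which equilibria are found by fixed-point
  iteration).
* **Softmax temperature 0.01** — q-value gaps decay like `γ^d` and are
  far below 1 beyond a few steps from the target, so a near-greedy softmax
  is required for the agent to exploit what it has learned at all; at
  temperature ~1 the policy is indistinguishable from uniform and no
  navigation is learned within the episode budget.  Calibrated once in
  pilot runs of the training phase, then frozen.
* **Reward update** — `w(s′) ← w(s′) + lr_w (r − w(s′))` applied at the
  *arrival* state (the reward is delivered on arrival; crediting the
  departure state would place the unit reward on the target's predecessor),
  with `lr_w = 1` by default, i.e. the observed reward overwrites the
  estimate.
* **M initialization** — identity, so the untrained value function is the
  immediate reward estimate.
* **Rest phase** — 10 steps between laps with no input and activities
  reset; no weight updates during rest.
* **17-node graph** — levels 1/4/12 with downward edges and a directed
  edge from every leaf back to the root.  A bidirectional-tree reading was
  examined and rejected: its symmetrized SR still navigates optimally, so
  it cannot show the directed-space disadvantage the protocol probes.
* **Sweep chain** — the circular walk is clockwise-biased (stay 0.1,
  cw 0.8, acw 0.1).  On a uniform ring the chain is reversible and the
  expected update for `α = −β` is *identically* zero, making the
  antidiagonal ratio 0/0; the bias makes the boundary well defined.

## Analyses

**Place-field shift.**  Per lap, each cell's firing-rate map is the mean
activity per state (negative linear-model activities rectified at zero —
rates are non-negative); its centre of mass (COM) is the activity-weighted
mean track position.  The headline statistic is mean COM over the last
five laps minus the first five; a per-lap series relative to lap 12 tracks
the time course.  Cells silent in any reference lap are excluded and
counted.  In continuous time, constant-velocity motion shifts the COM of a
successor feature by exactly `−v/γ_rate`; the discrete track matches this
within ~17% after converting `γ_rate = −ln(γ)/dt`, and the shift grows
with speed and with the discount.

**Navigation generalization.**  Phase 1 trains the agent to a random
target (fixed budget or an accuracy rule: mean suboptimality of the last 8
episodes below 2, hard cap 3000).  Phase 2 freezes `M`, resets `w`, draws
a new target, and relearns `w` only.  Suboptimality is episode steps minus
the directed BFS distance.  On symmetric grids the symmetric agent
generalizes better (pooled rank-sum, p ≪ 0.05 at 30 repetitions); on the
directed graph the ordering reverses *in the mean*.  There the symmetric
agent's failure is bimodal — most episodes near-optimal, a minority stuck
at the step cap — so rank statistics favour it even when its mean is
clearly worse; the directed-graph comparison is therefore asserted on
means, and the structural claim is verified separately in closed form
(greedy navigation from the symmetrized SR of the uniform-policy chain
fails on this graph with mean suboptimality ≈ 23 steps, while the
classical SR is optimal).

**Policy entropy.**  After every episode, the Shannon entropy of the
softmax policy is averaged over all states.  During training the symmetric
agent's policy is the more entropic; after the target switch the ordering
flips.

**Optimal-policy stability under symmetrization.**  For every target in
every symmetric fixture, a BFS-parent policy is completed with a uniform
restart at the target and its *experienced* edge flows (restart jumps are
not experienced transitions and are excluded — including them hands every
state a spurious backward edge into the target) are symmetrized and
renormalized.  Greedy actions under the resulting SR value function are
checked, with a relative tie tolerance (values decay like `γ^d`), to lie
on shortest paths; all four fixtures pass with zero violations.

## What the synthetic environments do and do not capture

Rings, tracks, grid worlds and the 17-node graph are exact discrete state
spaces with deterministic actions and fully known transition structure —
which is what makes closed-form oracles possible.  They do not model
continuous space, egocentric observation, sensory noise, reward magnitude
structure, or any within-episode change of the environment; the linear
track ignores running-speed variability and models the inter-lap rest as a
hard reset.  Passing tests therefore certify the algorithmic claims (which
representation is learned, and what it is good for), not quantitative
agreement with physiological recordings.

## Numerical choices and degenerate inputs

Row-stochasticity is validated to 1e-10 on construction and on file load;
stationarity solves are checked to 1e-8.  Ergodicity is established by
strong connectivity plus aperiodicity of the support graph before any
stationary quantity is computed, with named errors otherwise.  Divergence
in network runs (non-finite values or any |weight| > 1e6) raises with the
step index; in the sweep such runs enter their cell as +inf rather than
aborting it.  Zero-temperature action selection breaks argmax ties
uniformly.  Zero-mass rate profiles make the COM undefined and raise.

## Known limitations

Only the tabular parametrization of the generalized TD rule is
implemented (the function-approximation form is documented, not built).
The reduced repetition counts make the distribution-level comparisons
statistical reproductions of the protocol at scale, not bit-level figure
reconstructions; the directed-graph ordering in particular is a mean
effect with high per-repetition variance.  Eigendecomposition analyses of
the SR and continuous-state operators are out of scope.
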