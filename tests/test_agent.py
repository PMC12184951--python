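"""Tabular SR agent: TD updates, action selection, episodes and protocols."""

import numpy as np
import pytest

from symsr import (
    NavigationTask,
    SRAgentParams,
    SRAgentState,
    SuccessorAgent,
    blend_transitions,
    generalization_trial,
    grid_world,
    graph_distances,
    policy_entropy,
    q_values,
    run_episode,
    select_action,
    successor_matrix,
    td_fixed_policy_estimate,
    td_update,
    td_update_heterogeneous,
    td_update_noisy,
    train,
    uniform_policy_transitions,
    update_reward,
)
from symsr.markov import TransitionModel

from conftest import OPEN_5x5


def fresh(n=4, **kw):
    return SRAgentState.initial(n), SRAgentParams(**kw)


class TestTDUpdate:
    def test_classical_update_from_zero_touches_only_the_source_diagonal(self):
        state, params = fresh(alpha=1.0, beta=0.0, lr=0.2, gamma=0.7)
        state.M[:] = 0.0
        td_update(state, 1, 2, params)
        expected = np.zeros((4, 4))
        expected[1, 1] = 0.2
        np.testing.assert_allclose(state.M, expected)

    def test_symmetric_update_from_zero_touches_both_diagonals(self):
        state, params = fresh(alpha=0.5, beta=0.5, lr=0.2, gamma=0.7)
        state.M[:] = 0.0
        td_update(state, 1, 2, params)
        expected = np.zeros((4, 4))
        expected[1, 1] = 0.1
        expected[2, 2] = 0.1
        np.testing.assert_allclose(state.M, expected)

    def test_expected_update_vanishes_at_the_true_sr(self):
        # 3-state chain: E_{s'~P[s,.]}[dM] = 0 at M = (I - gamma P)^{-1}
        P = np.array([[0.1, 0.6, 0.3], [0.3, 0.2, 0.5], [0.5, 0.4, 0.1]])
        tm = TransitionModel(P)
        gamma = 0.7
        M_star = successor_matrix(tm, gamma).M
        params = SRAgentParams(alpha=1.0, beta=0.0, lr=1.0, gamma=gamma)
        for s in range(3):
            total = np.zeros((3, 3))
            for sp in range(3):
                state = SRAgentState(M_star.copy(), np.zeros(3))
                td_update(state, s, sp, params)
                total += P[s, sp] * (state.M - M_star)
            np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_self_transition_accumulates_both_terms_consistently(self):
        state, params = fresh(alpha=0.5, beta=0.5, lr=0.1, gamma=0.7)
        M0 = state.M.copy()
        td_update(state, 2, 2, params)
        # both half-updates act on row 2 and must use the pre-update row
        delta = 0.1 * (0.5 + 0.5) * ((1 + 0.7) * M0[2] - M0[2])
        delta[2] = 0.1 * (1 + 0.7 * M0[2, 2] - M0[2, 2])
        np.testing.assert_allclose(state.M[2], M0[2] + delta)


class TestTDVariants:
    def test_zero_noise_matches_the_deterministic_update(self):
        rng = np.random.default_rng(0)
        a, params = fresh(alpha=0.5, beta=0.5, noise_sigma=0.0, variant="noisy")
        b, _ = fresh(alpha=0.5, beta=0.5)
        td_update_noisy(a, 0, 1, params, rng)
        td_update(b, 0, 1, SRAgentParams(alpha=0.5, beta=0.5))
        np.testing.assert_array_equal(a.M, b.M)

    def test_noise_averages_out_over_many_draws(self):
        rng = np.random.default_rng(1)
        params = SRAgentParams(alpha=0.5, beta=0.5, lr=0.1, variant="noisy", noise_sigma=0.3)
        base = SRAgentState.initial(4)
        ref = SRAgentState(base.M.copy(), base.w.copy())
        td_update(ref, 0, 1, SRAgentParams(alpha=0.5, beta=0.5, lr=0.1))
        accum = np.zeros((4, 4))
        for _ in range(20_000):
            state = SRAgentState(base.M.copy(), base.w.copy())
            td_update_noisy(state, 0, 1, params, rng)
            accum += state.M
        np.testing.assert_allclose(accum / 20_000, ref.M, atol=5e-3)

    def test_heterogeneous_with_zero_spread_matches_classical(self):
        rng = np.random.default_rng(2)
        params = SRAgentParams(variant="heterogeneous", hetero_means=(1.0, 0.0), hetero_sigma=0.0)
        a = SRAgentState.initial(4, params, rng)
        b = SRAgentState.initial(4)
        td_update_heterogeneous(a, 1, 3, params)
        td_update(b, 1, 3, SRAgentParams(alpha=1.0, beta=0.0))
        np.testing.assert_allclose(a.M, b.M)

    def test_heterogeneous_parameters_are_nonnegative_and_reproducible(self):
        params = SRAgentParams(variant="heterogeneous", hetero_means=(0.5, 0.5), hetero_sigma=0.2)
        a = SRAgentState.initial(6, params, np.random.default_rng(7))
        b = SRAgentState.initial(6, params, np.random.default_rng(7))
        assert np.all(a.alpha_field >= 0) and np.all(a.beta_field >= 0)
        np.testing.assert_array_equal(a.alpha_field, b.alpha_field)

    def test_uninitialized_heterogeneous_parameters_raise(self):
        state = SRAgentState.initial(4)
        with pytest.raises(ValueError, match="not initialized"):
            td_update_heterogeneous(state, 0, 1, SRAgentParams(variant="heterogeneous"))

    def test_interpolated_parameters_span_classical_to_symmetric(self):
        p0 = SRAgentParams.interpolated(0.0)
        p1 = SRAgentParams.interpolated(1.0)
        assert (p0.alpha, p0.beta) == (1.0, 0.0)
        assert (p1.alpha, p1.beta) == (0.5, 0.5)


class TestRewardAndValues:
    def test_full_rate_overwrites_the_estimate(self):
        state = SRAgentState.initial(3)
        update_reward(state, 1, 1.0, lr_w=1.0)
        assert state.w[1] == 1.0 and state.w[0] == 0.0

    def test_matching_reward_leaves_estimate_unchanged(self):
        state = SRAgentState.initial(3)
        state.w[2] = 0.4
        update_reward(state, 2, 0.4, lr_w=0.5)
        assert state.w[2] == pytest.approx(0.4)

    def test_repeated_updates_approach_the_reward_geometrically(self):
        state = SRAgentState.initial(3)
        for k in range(1, 6):
            update_reward(state, 0, 1.0, lr_w=0.5)
            assert state.w[0] == pytest.approx(1 - 0.5 ** k)

    def test_zero_reward_vector_gives_zero_q(self, open_grid_5x5):
        _, actions = open_grid_5x5
        state = SRAgentState.initial(actions.n_states)
        np.testing.assert_array_equal(q_values(state, 3, actions), np.zeros(4))

    def test_equal_value_successors_give_equal_q(self, open_grid_5x5):
        _, actions = open_grid_5x5
        state = SRAgentState.initial(actions.n_states)
        state.w[:] = 1.0  # every state equally rewarding
        q = q_values(state, 12, actions)  # centre state
        np.testing.assert_allclose(q, q[0])

    def test_greedy_action_under_closed_form_sr_decreases_distance(self, open_grid_5x5):
        space, actions = open_grid_5x5
        tm = uniform_policy_transitions(space, actions)
        D = graph_distances(actions)
        target = 7
        M = successor_matrix(tm, 0.7).M
        state = SRAgentState(M, np.zeros(actions.n_states))
        state.w[target] = 1.0
        for s in range(actions.n_states):
            if s == target:
                continue
            q = q_values(state, s, actions)
            greedy = actions.next_state[s][np.argmax(q)]
            assert D[greedy, target] == D[s, target] - 1


class TestActionSelection:
    def test_equal_q_samples_uniformly(self):
        rng = np.random.default_rng(0)
        picks = [select_action(np.zeros(4), 1.0, rng) for _ in range(4000)]
        counts = np.bincount(picks, minlength=4) / 4000
        np.testing.assert_allclose(counts, 0.25, atol=0.03)

    def test_zero_temperature_is_argmax_with_uniform_ties(self):
        rng = np.random.default_rng(1)
        q = np.array([0.0, 1.0, 1.0, 0.2])
        picks = {select_action(q, 0.0, rng) for _ in range(200)}
        assert picks == {1, 2}

    def test_seeded_selection_is_reproducible(self):
        q = np.array([0.1, 0.5, 0.2])
        a = [select_action(q, 0.5, np.random.default_rng(3)) for _ in range(10)]
        b = [select_action(q, 0.5, np.random.default_rng(3)) for _ in range(10)]
        assert a == b

    def test_non_finite_q_raises(self):
        with pytest.raises(ValueError, match="finite"):
            select_action(np.array([np.nan, 0.0]), 1.0, np.random.default_rng(0))


class TestPolicyEntropy:
    def test_uniform_policy_has_log_four_entropy(self, open_grid_5x5):
        _, actions = open_grid_5x5
        state = SRAgentState.initial(actions.n_states)
        state.M[:] = 0.0  # all q equal -> uniform softmax
        assert policy_entropy(state, actions, 1.0) == pytest.approx(np.log(4))

    def test_hand_computed_four_action_distribution(self):
        p = np.array([0.7, 0.1, 0.1, 0.1])
        expected = -np.sum(p * np.log(p))
        # build q so softmax(q) = p exactly: q = log p, temperature 1
        from symsr.envs import ActionModel

        nxt = np.array([[0, 1, 2, 3], [0, 1, 2, 3], [0, 1, 2, 3], [0, 1, 2, 3]])
        actions = ActionModel(("a", "b", "c", "d"), nxt)
        state = SRAgentState(np.eye(4), np.log(p))
        assert policy_entropy(state, actions, 1.0) == pytest.approx(expected)

    def test_sharp_temperature_drives_entropy_to_zero(self, open_grid_5x5):
        _, actions = open_grid_5x5
        n = actions.n_states
        rng = np.random.default_rng(0)
        state = SRAgentState(rng.random((n, n)), rng.random(n))
        assert policy_entropy(state, actions, 1e-6) == pytest.approx(0.0, abs=1e-3)


class TestEpisodesAndTraining:
    def make_perfect_agent(self, open_grid, target, gamma=0.7):
        space, actions = open_grid
        tm = uniform_policy_transitions(space, actions)
        M = successor_matrix(tm, gamma).M
        state = SRAgentState(M, np.zeros(actions.n_states))
        state.w[target] = 1.0
        return state, actions

    def test_perfect_agent_at_low_temperature_takes_shortest_paths(self, open_grid_5x5):
        state, actions = self.make_perfect_agent(open_grid_5x5, target=0)
        task = NavigationTask(actions, 0)
        D = graph_distances(actions)
        params = SRAgentParams(temperature=1e-9)
        rng = np.random.default_rng(0)
        for start in (6, 12, 24):
            log = run_episode(
                state, task, params, rng, learn_M=False, learn_w=False, start=start
            )
            assert log.steps == D[start, 0]
            assert log.terminal

    def test_zero_max_steps_truncates_immediately(self, open_grid_5x5):
        _, actions = open_grid_5x5
        task = NavigationTask(actions, 0, max_steps=0)
        state = SRAgentState.initial(actions.n_states)
        log = run_episode(state, task, SRAgentParams(), np.random.default_rng(0))
        assert log.steps == 0 and not log.terminal

    def test_logged_entropy_matches_recomputation_at_episode_end(self, open_grid_5x5):
        _, actions = open_grid_5x5
        task = NavigationTask(actions, 5)
        state = SRAgentState.initial(actions.n_states)
        params = SRAgentParams()
        log = run_episode(state, task, params, np.random.default_rng(1))
        assert log.entropy == pytest.approx(
            policy_entropy(state, actions, params.temperature)
        )

    def test_fixed_episode_budget_is_respected(self, open_grid_5x5):
        _, actions = open_grid_5x5
        task = NavigationTask(actions, 3)
        state = SRAgentState.initial(actions.n_states)
        logs = train(state, task, SRAgentParams(), np.random.default_rng(0), ("fixed_episodes", 1))
        assert len(logs) == 1

    def test_accuracy_rule_stops_after_window_for_an_optimal_agent(self, open_grid_5x5):
        state, actions = self.make_perfect_agent(open_grid_5x5, target=0)
        task = NavigationTask(actions, 0)
        params = SRAgentParams(temperature=1e-9)
        logs = train(
            state, task, params, np.random.default_rng(0), ("accuracy", 8, 2.0),
            learn_M=False,
        )
        assert len(logs) == 8

    def test_generalization_freezes_the_sr(self, open_grid_5x5):
        _, actions = open_grid_5x5
        task = NavigationTask(actions, 0)
        state = SRAgentState.initial(actions.n_states)
        params = SRAgentParams()
        M_before = state.M.copy()
        logs = generalization_trial(state, task, 10, params, np.random.default_rng(0), episodes=3)
        np.testing.assert_array_equal(state.M, M_before)
        assert all(lg.target == 10 for lg in logs)
        assert all(lg.suboptimality >= 0 for lg in logs)

    def test_model_results_summary_reports_phases(self, open_grid_5x5):
        _, actions = open_grid_5x5
        agent = SuccessorAgent(actions, target=0, params=SRAgentParams())
        res = agent.fit(stop_rule=("fixed_episodes", 3), seed=0, new_target=7,
                        generalization_episodes=2)
        text = res.summary()
        assert "training episodes" in text and "generalization" in text
        df = res.frame()
        assert set(df["phase"]) == {"train", "generalize"}


class TestFixedPolicyTD:
    def test_classical_and_symmetric_estimates_converge_to_their_blends(self, open_grid_5x5):
        space, actions = open_grid_5x5
        tm = uniform_policy_transitions(space, actions)
        gamma = 0.7
        for rule in ((1.0, 0.0), (0.5, 0.5)):
            target = successor_matrix(blend_transitions(tm, rule), gamma).M
            M = td_fixed_policy_estimate(tm, rule, gamma, T=30_000, seed=11)
            assert np.max(np.abs(M - target)) < 0.08

    def test_symmetric_estimate_on_a_biased_ring_matches_the_symmetrized_sr(self, biased_ring):
        gamma = 0.7
        target = successor_matrix(blend_transitions(biased_ring, (0.5, 0.5)), gamma).M
        wrong = successor_matrix(biased_ring, gamma).M
        M = td_fixed_policy_estimate(biased_ring, (0.5, 0.5), gamma, T=30_000, seed=12)
        assert np.max(np.abs(M - target)) < np.max(np.abs(M - wrong))
        assert np.max(np.abs(M - target)) < 0.08
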