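"""Q-learning model: updates, softmax, traces, likelihood, fitting, probes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import banditlens as bl
from banditlens.agents import BehaviouralRecord
from banditlens.qlearning import (
    QParams,
    action_probs,
    fit,
    negative_log_likelihood,
    predict_and_score,
    q_update,
    simulate_probe,
    trace,
)


def _record(actions, rewards, missed=None, pid="p0"):
    actions = np.asarray(actions)
    missed = np.zeros(len(actions), bool) if missed is None else np.asarray(missed)
    a = np.where(missed, -1, actions)
    r = np.where(missed, np.nan, np.asarray(rewards, float))
    return BehaviouralRecord(pid, 1, a, r, missed)


class TestUpdateAndSoftmax:
    def test_delta_rule_arithmetic(self):
        q = q_update(np.full(4, 50.0), 1, 40.0, 0.5)
        assert q[0] == pytest.approx(45.0) and np.all(q[1:] == 50.0)

    @pytest.mark.parametrize("alpha,expected", [(0.0, 50.0), (1.0, 40.0)])
    def test_alpha_extremes(self, alpha, expected):
        assert q_update(np.full(4, 50.0), 2, 40.0, alpha)[1] == pytest.approx(expected)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            q_update(np.full(4, 50.0), 1, 40.0, 1.5)

    def test_softmax_symmetry_and_analytic_value(self):
        assert np.allclose(action_probs(np.full(4, 50.0), 0.7), 0.25)
        p = action_probs(np.array([60.0, 50, 50, 50]), 0.1)
        assert p[0] == pytest.approx(np.e / (np.e + 3), abs=1e-9)
        assert np.allclose(p[1:], 1 / (np.e + 3))

    def test_softmax_greedy_limit_and_stability(self):
        p = action_probs(np.array([60.0, 50, 50, 50]), 1000.0)
        assert p[0] > 0.999999
        assert np.isfinite(p).all()

    @given(
        q=st.lists(st.floats(-100, 200), min_size=4, max_size=4),
        beta=st.floats(0.001, 5.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_softmax_is_a_distribution(self, q, beta):
        p = action_probs(np.array(q), beta)
        assert p.sum() == pytest.approx(1.0, abs=1e-9) and (p >= 0).all()


class TestTrace:
    def test_equal_rewards_all_actions_gives_uniform(self):
        rec = _record([1, 2, 3, 4], [40] * 4)
        for alpha, beta in [(0.1, 0.05), (0.7, 0.3), (1.0, 0.9)]:
            tr = trace(rec, QParams(alpha, beta))
            # after updating each option once with reward 40 all values equal
            q_final = bl.qlearning.q_update(tr.q_values[3], 4, 40.0, alpha)
            assert np.allclose(q_final, 50 - 10 * alpha)
            assert np.allclose(bl.qlearning.action_probs(q_final, beta), 0.25)

    def test_initialisation_at_fifty(self):
        tr = trace(_record([1, 1], [40, 40]), QParams(0.5, 0.1))
        assert np.all(tr.q_values[0] == 50.0)

    def test_missed_trials_freeze_values(self):
        rec = _record([0, 0, 0], [0, 0, 0], missed=[True] * 3)
        tr = trace(rec, QParams(0.5, 0.1))
        assert np.all(tr.q_values == 50.0)

    def test_geometric_recursion_closed_form(self):
        rec = _record([1, 1, 1, 1], [40] * 4)
        tr = trace(rec, QParams(0.5, 0.1))
        q_final = bl.qlearning.q_update(tr.q_values[3], 1, 40.0, 0.5)
        assert q_final[0] == pytest.approx(50 * 0.5**4 + 40 * (1 - 0.5**4))  # 40.625

    def test_order_sensitivity(self):
        """Permuting trials changes the trace (history matters)."""
        fwd = trace(_record([1, 1], [10, 90]), QParams(0.5, 0.1))
        rev = trace(_record([1, 1], [90, 10]), QParams(0.5, 0.1))
        q_fwd = bl.qlearning.q_update(fwd.q_values[1], 1, 90.0, 0.5)
        q_rev = bl.qlearning.q_update(rev.q_values[1], 1, 10.0, 0.5)
        assert not np.allclose(q_fwd, q_rev)

    def test_q_values_bounded_by_reward_range(self, small_population):
        params = QParams(0.8, 0.2)
        for rec in small_population[:10]:
            tr = trace(rec, params)
            assert tr.q_values.min() >= 1.0 and tr.q_values.max() <= 98.0


class TestLikelihood:
    def test_uniform_limit(self):
        rec = _record([3], [40])
        nll = negative_log_likelihood([rec], QParams(0.5, 1e-9))
        assert nll == pytest.approx(np.log(4), abs=1e-6)

    def test_n_trials_times_log4(self):
        rec = _record([1, 2, 3, 4, 1], [40] * 5)
        nll = negative_log_likelihood([rec], QParams(0.5, 1e-9))
        assert nll == pytest.approx(5 * np.log(4), abs=1e-5)

    def test_peaks_near_generating_parameters(self, payoff):
        recs = bl.agents.generate_population(
            50, mixture={"q_learning": 1.0}, payoffs=[payoff], seed=3,
            parameter_ranges={"alpha": (0.3, 0.3), "beta": (0.15, 0.15)},
        )
        at_truth = negative_log_likelihood(recs, QParams(0.3, 0.15))
        assert at_truth <= negative_log_likelihood(recs, QParams(0.3, 0.30))
        assert at_truth <= negative_log_likelihood(recs, QParams(0.3, 0.075))


class TestFit:
    def test_parameter_recovery(self, payoff):
        recs = bl.agents.generate_population(
            200, mixture={"q_learning": 1.0}, payoffs=[payoff], seed=4,
            parameter_ranges={"alpha": (0.3, 0.3), "beta": (0.15, 0.15)},
        )
        result = fit(recs, n_starts=3, seed=0)
        assert result.params.alpha == pytest.approx(0.3, abs=0.05)
        assert result.params.beta == pytest.approx(0.15, abs=0.03)

    def test_random_agents_fit_to_noise_limit(self, payoff):
        recs = bl.agents.generate_population(
            50, mixture={"random": 1.0}, payoffs=[payoff], seed=5
        )
        result = fit(recs, n_starts=3, seed=0)
        assert result.params.beta <= 0.01

    def test_parameters_within_declared_bounds(self, small_population):
        result = fit(small_population, n_starts=2, seed=1)
        assert 0.0 <= result.params.alpha <= 1.0
        assert 0.0 < result.params.beta <= 1.0


class TestPredictAndScore:
    def test_greedy_agent_near_perfect_after_burn_in(self):
        # one statically-best option, deterministic greedy data
        actions = [1] * 30
        rewards = [90.0] * 30
        score = predict_and_score([_record(actions, rewards)], QParams(0.5, 0.2))
        late = score.table[score.table["trial"] > 5]
        assert late["correct"].all()

    def test_all_missed_record_scores_absent(self):
        rec = _record([0, 0], [0, 0], missed=[True, True])
        score = predict_and_score([rec], QParams(0.5, 0.2))
        assert score.accuracy is None

    def test_cycle_agent_scores_near_chance(self, payoff):
        recs = []
        for i in range(20):
            spec = bl.agents.AgentSpec(
                kind="pattern", pattern_type="cycle", pattern_options=(1, 2, 3, 4),
            )
            rec = bl.task.run_episode(
                bl.agents.make_policy(spec), payoff,
                bl.task.EpisodeConfig(n_trials=150, seed=i),
            )
            rec.participant_id = f"c{i}"
            recs.append(rec)
        params = fit(recs, n_starts=2, seed=0).params
        score = predict_and_score(recs, params)
        assert abs(score.accuracy - 0.25) < 0.1

    def test_first_trial_flagged(self, small_population):
        score = predict_and_score(small_population[:3], QParams(0.3, 0.1))
        flagged = score.table[score.table["first_trial"]]
        assert (flagged["trial"] == 1).all()


class TestSimulateProbe:
    def test_all_different_equal_rewards_is_uniform(self):
        for alpha, beta in [(0.1, 0.05), (0.5, 0.2), (0.9, 0.8)]:
            p = simulate_probe((1, 2, 3, 4), (40, 40, 40, 40), QParams(alpha, beta))
            assert np.allclose(p, 0.25, atol=1e-12)

    def test_ascending_rewards_favour_last_action(self):
        p = simulate_probe((1, 2, 3, 4), (20, 30, 70, 80), QParams(0.3, 0.15))
        assert p.argmax() == 3

    def test_descending_rewards_favour_first_action(self):
        p = simulate_probe((1, 2, 3, 4), (80, 60, 40, 20), QParams(0.3, 0.15))
        assert p.argmax() == 0
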