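"""Task environment and generative agent: choice rule, learning rule, boosts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakebandit import (
    AgentParams,
    BoostContractError,
    TaskConfig,
    apply_social_boost,
    q_update,
    simulate_block,
    simulate_session,
    softmax_choice_prob,
)

finite_q = st.floats(min_value=-20, max_value=20, allow_nan=False)


class TestSoftmax:
    @pytest.mark.parametrize("q", [0.0, 4.75, -3.2])
    def test_equal_values_give_half(self, q):
        assert softmax_choice_prob(q, q, beta=8.0) == pytest.approx(0.5)

    @given(q_a=finite_q, q_b=finite_q)
    @settings(derandomize=True)
    def test_zero_precision_is_random_choice(self, q_a, q_b):
        assert softmax_choice_prob(q_a, q_b, beta=0.0) == 0.5

    def test_hand_evaluated_probability(self):
        # direct evaluation: p = 1 / (1 + exp(-beta * (q_a - q_b)))
        assert softmax_choice_prob(5.5, 4.0, beta=1.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-1.5)), rel=1e-12
        )

    @given(q_a=finite_q, q_b=finite_q, beta=st.floats(0, 50), shift=finite_q)
    @settings(derandomize=True)
    def test_probabilities_sum_to_one_and_shift_invariant(self, q_a, q_b, beta, shift):
        p_a = softmax_choice_prob(q_a, q_b, beta)
        p_b = softmax_choice_prob(q_b, q_a, beta)
        assert 0.0 <= p_a <= 1.0
        assert p_a + p_b == pytest.approx(1.0, abs=1e-12)
        assert softmax_choice_prob(q_a + shift, q_b + shift, beta) == pytest.approx(
            p_a, abs=1e-9
        )

    def test_high_precision_approaches_argmax(self):
        assert softmax_choice_prob(5.0, 4.0, beta=50.0) > 0.999999

    @pytest.mark.parametrize("bad", [math.nan, math.inf])
    def test_non_finite_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            softmax_choice_prob(bad, 4.0, 1.0)


class TestQUpdate:
    def test_zero_prediction_error_is_identity(self):
        assert q_update(4.75, 4.75, 0.3) == 4.75

    def test_full_update_jumps_to_reward(self):
        assert q_update(3.0, 7.0, 1.0) == 7.0

    def test_hand_evaluated_update(self):
        assert q_update(3.0, 7.0, 0.25) == pytest.approx(4.0)

    @given(
        q=finite_q,
        r=finite_q,
        alpha=st.floats(0, 1, allow_nan=False),
    )
    @settings(derandomize=True)
    def test_update_stays_between_old_value_and_reward(self, q, r, alpha):
        new = q_update(q, r, alpha)
        assert min(q, r) - 1e-9 <= new <= max(q, r) + 1e-9

    @pytest.mark.parametrize("alpha", [-0.1, 1.2])
    def test_learning_rate_outside_unit_interval_rejected(self, alpha):
        with pytest.raises(ValueError):
            q_update(4.0, 5.0, alpha)


class TestSocialBoost:
    def test_zero_boost_is_identity(self):
        state = (4.1, 5.0, 8.6)
        assert apply_social_boost(state, 0, qboost=0.0, bboost=8.6, q_max=7.2) == state

    def test_full_boost_sets_ceiling(self):
        q_a, q_b, beta = apply_social_boost((4.1, 5.0, 8.6), 0, 1.0, 50.0, q_max=7.2)
        assert q_a == pytest.approx(7.2)
        assert q_b == 5.0
        assert beta == 50.0

    def test_partial_boost_is_convex_combination(self):
        q_a, q_b, _ = apply_social_boost((3.0, 4.0, 8.6), 1, 0.5, 8.6, q_max=8.0)
        assert q_b == pytest.approx(6.0)
        assert q_a == 3.0

    def test_control_blocks_are_never_boosted(self):
        with pytest.raises(BoostContractError):
            apply_social_boost((4.0, 4.0, 8.6), 0, 1.0, 50.0, 7.2, condition="control")

    def test_boost_applies_at_most_once(self):
        with pytest.raises(BoostContractError):
            apply_social_boost((4.0, 4.0, 8.6), 0, 1.0, 50.0, 7.2, already_applied=True)


class TestSimulateBlock:
    def test_block_length_and_determinism(self, config, exploiter):
        b1 = simulate_block(config, exploiter, "advice", rng_seed=7)
        b2 = simulate_block(config, exploiter, "advice", rng_seed=7)
        assert len(b1.trials) == config.n_trials
        assert [t.choice for t in b1.trials] == [t.choice for t in b2.trials]
        assert [t.reward for t in b1.trials] == [t.reward for t in b2.trials]

    def test_control_blocks_ignore_boost_parameters(self, config):
        base = dict(alpha=0.4, beta=5.0)
        no_boost = AgentParams(**base)
        big_boost = AgentParams(
            **base, qboost_advice=1.0, qboost_observation=1.0,
            bboost_advice=50.0, bboost_observation=50.0,
        )
        b1 = simulate_block(config, no_boost, "control", rng_seed=11)
        b2 = simulate_block(config, big_boost, "control", rng_seed=11)
        assert [t.choice for t in b1.trials] == [t.choice for t in b2.trials]

    def test_social_block_with_neutral_boost_matches_control(self, config):
        """qboost=0 and bboost=beta make a social block distributionally a control block."""
        params = AgentParams(
            alpha=0.4, beta=5.0, qboost_advice=0.0, bboost_advice=5.0
        )
        control = simulate_block(config, params, "control", rng_seed=23, good_lake=1)
        social = simulate_block(config, params, "advice", rng_seed=23, good_lake=1)
        assert [t.choice for t in control.trials] == [t.choice for t in social.trials]
        assert [t.q_a for t in control.trials] == [t.q_a for t in social.trials]

    def test_reward_moments_match_generative_means(self, config, explorer):
        rewards = {0: [], 1: []}
        root = np.random.SeedSequence(99)
        params = AgentParams(alpha=0.3, beta=0.1)  # near-random sampling of both lakes
        for child in root.spawn(800):
            block = simulate_block(config, params, "control", child)
            for t in block.trials:
                lake_is_good = int(t.choice == block.good_lake)
                rewards[lake_is_good].append(t.reward)
        for is_good, mean in ((1, config.mean_good), (0, config.mean_bad)):
            draws = np.array(rewards[is_good])
            se = config.reward_sd / math.sqrt(len(draws))
            assert abs(draws.mean() - mean) < 3 * se
            assert abs(draws.std(ddof=1) - config.reward_sd) < 0.05

    def test_exploiter_follows_cue_and_exploits_argmax(self, config, exploiter):
        """Full value boost makes trial 5 track the cue; ceiling precision
        makes every later choice the argmax of the entering Q-values.

        (Post-cue *good-lake* rate is high but not 1: a run of low draws can
        flip Q-dominance and the argmax agent tracks it.)
        """
        n5 = n5_good = 0
        n_post = n_argmax = n_post_good = 0
        for child in np.random.SeedSequence(5).spawn(300):
            block = simulate_block(config, exploiter, "advice", child)
            for t in block.trials:
                if t.trial == config.cue_after_trial + 1:
                    n5 += 1
                    n5_good += t.choice == block.good_lake
                elif t.trial > config.cue_after_trial + 1:
                    n_post += 1
                    n_argmax += t.choice == (0 if t.q_a >= t.q_b else 1)
                    n_post_good += t.choice == block.good_lake
        assert n5_good / n5 > 0.97
        assert n_argmax / n_post > 0.99
        assert n_post_good / n_post > 0.85


class TestSimulateSession:
    def test_session_has_45_trials_and_is_reproducible(self, config, explorer):
        order = ("control", "observation", "advice")
        s1 = simulate_session(config, explorer, order, rng_seed=3)
        s2 = simulate_session(config, explorer, order, rng_seed=3)
        assert sum(len(b.trials) for b in s1) == 45
        assert [b.condition for b in s1] == list(order)
        assert [b.block_order for b in s1] == [1, 2, 3]
        for b1, b2 in zip(s1, s2):
            assert [t.reward for t in b1.trials] == [t.reward for t in b2.trials]

    def test_block_position_seeding_is_order_invariant(self, config):
        """Permuting conditions must not perturb per-position reward streams."""
        params = AgentParams(alpha=0.4, beta=5.0, qboost_advice=0.0, bboost_advice=5.0)
        s1 = simulate_session(config, params, ("advice", "observation", "control"), 17)
        s2 = simulate_session(config, params, ("control", "observation", "advice"), 17)
        # position 2 runs 'observation' in both sessions: identical blocks
        assert [t.reward for t in s1[1].trials] == [t.reward for t in s2[1].trials]
        # positions 1/3 swap a neutral-boost advice block for a control block:
        # same good lake and same potential-yield stream by construction
        assert s1[0].good_lake == s2[0].good_lake
        assert s1[2].good_lake == s2[2].good_lake

    def test_malformed_permutation_rejected(self, config, explorer):
        with pytest.raises(ValueError):
            simulate_session(config, explorer, ("control", "control", "advice"), 3)
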