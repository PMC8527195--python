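"""Likelihood correctness (against an arbitrary-precision oracle) and fitting."""

import math
from dataclasses import replace

import mpmath
import numpy as np
import pytest

from lakebandit import (
    AgentParams,
    BlockData,
    FitSettings,
    TaskConfig,
    TrialRecord,
    block_nll,
    classify_bboost,
    cohort_fit,
    fit_participant,
    simulate_block,
    simulate_session,
)
from lakebandit.task import PARAM_BOUNDS


def oracle_block_nll(block, params, config):
    """Naive arbitrary-precision re-implementation of the teacher-forced NLL.

    Written independently of the package's log-sum-exp path: plain softmax
    evaluated at 50 decimal digits.
    """
    with mpmath.workdps(50):
        q = {0: mpmath.mpf(config.q_init), 1: mpmath.mpf(config.q_init)}
        beta = mpmath.mpf(params.beta)
        social = block.condition != "control"
        qboost = mpmath.mpf(params.qboost_for(block.condition)) if social else 0
        bboost = mpmath.mpf(params.bboost_for(block.condition)) if social else beta
        if config.q_max_mode == "fixed":
            q_max = mpmath.mpf(config.q_max_fixed)
        else:
            pre = [t.reward for t in block.trials if t.trial <= config.cue_after_trial]
            q_max = mpmath.mpf(max(pre)) if pre else mpmath.mpf(config.q_init)
        boosted = False
        nll = mpmath.mpf(0)
        for t in block.trials:
            if social and not boosted and t.trial > config.cue_after_trial:
                q[block.cue_target] = (1 - qboost) * q[block.cue_target] + qboost * q_max
                beta = bboost
                boosted = True
            ea, eb = mpmath.e ** (beta * q[0]), mpmath.e ** (beta * q[1])
            p = ea / (ea + eb) if t.choice == 0 else eb / (ea + eb)
            nll -= mpmath.log(p)
            q[t.choice] = q[t.choice] + mpmath.mpf(params.alpha) * (t.reward - q[t.choice])
        return float(nll)


def random_block(rng, config, condition):
    params = AgentParams(
        alpha=float(rng.uniform(0.05, 0.95)),
        beta=float(rng.uniform(0.1, 15)),
        qboost_advice=float(rng.uniform(0, 1)),
        qboost_observation=float(rng.uniform(0, 1)),
        bboost_advice=float(rng.uniform(0.1, 50)),
        bboost_observation=float(rng.uniform(0.1, 50)),
    )
    seed = int(rng.integers(2**31))
    return simulate_block(config, params, condition, seed), params


class TestBlockNll:
    def test_zero_precision_gives_n_log_2(self, config):
        block = simulate_block(config, AgentParams(alpha=0.5, beta=0.1), "control", 3)
        uniform = AgentParams(alpha=0.5, beta=0.0)
        nll = block_nll(block, uniform, config)
        assert nll == pytest.approx(config.n_trials * math.log(2), rel=1e-12)

    def test_uninformative_trials_add_log2_each(self, config):
        """Every beta=0 trial contributes exactly log 2, regardless of data."""
        uniform = AgentParams(alpha=0.5, beta=0.0)
        full = simulate_block(config, AgentParams(alpha=0.5, beta=0.1), "control", 5)
        for k in (1, 5, 10):
            shorter = BlockData(
                condition="control", block_order=1, good_lake=full.good_lake,
                cue_target=None, trials=full.trials[:k],
            )
            assert block_nll(full, uniform, config) - block_nll(
                shorter, uniform, config
            ) == pytest.approx((config.n_trials - k) * math.log(2), rel=1e-12)

    def test_two_trial_block_matches_hand_computation(self, config):
        """q_init=4.75, alpha=0.25, beta=1, rewards {7,3}, choices {A,A}."""
        block = BlockData(
            condition="control", block_order=1, good_lake=0, cue_target=None,
            trials=[TrialRecord(1, 0, 7.0), TrialRecord(2, 0, 3.0)],
        )
        params = AgentParams(alpha=0.25, beta=1.0)
        # trial 1: equal Qs, p = 1/2; Q_A <- 4.75 + 0.25*(7-4.75) = 5.3125
        # trial 2: p = sigmoid(1 * (5.3125 - 4.75)) = sigmoid(0.5625)
        q_a_after = 4.75 + 0.25 * (7.0 - 4.75)
        assert q_a_after == pytest.approx(5.3125)
        expected = -(math.log(0.5) + math.log(1 / (1 + math.exp(-0.5625))))
        assert block_nll(block, params, config) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("condition", ["control", "observation", "advice"])
    def test_matches_arbitrary_precision_oracle(self, config, condition):
        rng = np.random.default_rng(42)
        for _ in range(17):  # ~50 blocks across the three conditions
            block, params = random_block(rng, config, condition)
            assert block_nll(block, params, config) == pytest.approx(
                oracle_block_nll(block, params, config), abs=1e-9
            )

    def test_oracle_agreement_under_fixed_q_max(self):
        config = TaskConfig(q_max_mode="fixed", q_max_fixed=7.2)
        rng = np.random.default_rng(7)
        for _ in range(10):
            block, params = random_block(rng, config, "advice")
            assert block_nll(block, params, config) == pytest.approx(
                oracle_block_nll(block, params, config), abs=1e-9
            )

    def test_empty_block_rejected(self, config):
        block = BlockData(
            condition="control", block_order=1, good_lake=0, cue_target=None, trials=[]
        )
        with pytest.raises(ValueError):
            block_nll(block, AgentParams(alpha=0.5, beta=1.0), config)

    def test_convex_in_beta_for_fixed_trajectory(self, config):
        """Teacher forcing fixes the Q path, so the control NLL is convex in beta."""
        block = simulate_block(config, AgentParams(alpha=0.5, beta=3.0), "control", 8)
        grid = np.linspace(0.1, 30, 120)
        nll = np.array(
            [block_nll(block, AgentParams(alpha=0.5, beta=float(b)), config) for b in grid]
        )
        second_diff = np.diff(nll, n=2)
        assert np.all(second_diff > -1e-8)


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected", [(45.0, "high"), (40.0, "low"), (12.0, "low"), (40.0001, "high")]
    )
    def test_threshold_rule(self, value, expected):
        assert classify_bboost(value) == expected

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            classify_bboost(51.0)
        with pytest.raises(ValueError):
            classify_bboost(0.0)


class TestFitParticipant:
    @pytest.fixture
    def blocks(self, config, exploiter):
        return simulate_session(
            config, exploiter, ("control", "observation", "advice"), rng_seed=15
        )

    def test_fit_is_deterministic_under_start_seed(self, config, blocks):
        settings = FitSettings(n_starts=3, start_seed=7)
        f1 = fit_participant(blocks, settings, config)
        f2 = fit_participant(blocks, settings, config)
        assert f1.params_hat == f2.params_hat
        assert f1.nll == f2.nll

    def test_estimates_respect_bounds(self, config, blocks):
        fit = fit_participant(blocks, FitSettings(n_starts=4, start_seed=1), config)
        for name in PARAM_BOUNDS:
            lo, hi = PARAM_BOUNDS[name]
            value = getattr(fit.params_hat, name)
            assert lo <= value <= hi

    def test_missing_condition_rejected(self, config, blocks):
        with pytest.raises(ValueError):
            fit_participant(blocks[:2], FitSettings(n_starts=1), config)

    def test_exploiter_classified_high_in_majority_of_replicates(self, config, exploiter):
        """Agents at the precision ceiling are recovered as 'high' from 15-trial blocks."""
        n_high = 0
        n_rep = 24
        for i in range(n_rep):
            blocks = simulate_session(
                config, exploiter, ("control", "observation", "advice"), rng_seed=1000 + i
            )
            fit = fit_participant(blocks, FitSettings(n_starts=6, start_seed=i), config)
            n_high += fit.bboost_class_advice == "high"
        assert n_high > n_rep / 2

    def test_fit_improves_on_wrong_parameters(self, config, blocks, exploiter):
        from lakebandit import session_nll

        fit = fit_participant(blocks, FitSettings(n_starts=6, start_seed=2), config)
        wrong = AgentParams(alpha=0.1, beta=0.5)
        assert fit.nll <= session_nll(blocks, wrong, config)
        assert fit.nll <= session_nll(blocks, exploiter, config) + 1e-6


class TestCohortFit:
    def test_empty_cohort_gives_empty_table(self, config):
        fits = cohort_fit({}, FitSettings(n_starts=1), config)
        assert len(fits) == 0
        assert "participant_id" in fits.columns

    def test_participant_with_missing_block_skipped(self, config, exploiter, caplog):
        session = simulate_session(
            config, exploiter, ("control", "observation", "advice"), 5
        )
        cohort = {"good": session, "bad": session[:2]}
        fits = cohort_fit(cohort, FitSettings(n_starts=2, start_seed=3), config)
        assert list(fits["participant_id"]) == ["good"]

    def test_cohort_fit_reproducible(self, config, exploiter, explorer):
        cohort = {
            "a": simulate_session(config, exploiter, ("control", "observation", "advice"), 1),
            "b": simulate_session(config, explorer, ("advice", "control", "observation"), 2),
        }
        t1 = cohort_fit(cohort, FitSettings(n_starts=2, start_seed=9), config)
        t2 = cohort_fit(cohort, FitSettings(n_starts=2, start_seed=9), config)
        assert t1.equals(t2)
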