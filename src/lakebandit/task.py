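"""Task environment and generative agent for the two-lake fishing task.

The task is a two-armed bandit framed as choosing which of two lakes to fish
from.  One lake has a higher mean yield than the other; yields are Gaussian
with a common standard deviation, so single outcomes are only weakly
diagnostic.  A block lasts 15 trials.  In the two social conditions
(*observation* and *advice*) a single, always-accurate social cue pointing at
the good lake is shown after the feedback of trial 4; the *control* condition
has no cue.

The agent is a delta-rule Q-learner with softmax choice.  Social information
acts through two one-time changes applied between the feedback of the cue
trial and the next choice:

* a **value boost**: the cued lake's Q-value is moved a fraction ``qboost``
  of the way toward a ceiling ``q_max`` (``qboost = 1`` sets it exactly to
  the ceiling, i.e. the "maximum level");
* a **precision boost**: the softmax precision is *replaced* by ``bboost``
  for every remaining trial of the block.

Both changes happen exactly once per social block and never in control
blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CONDITIONS",
    "PARAM_BOUNDS",
    "PARAM_ORDER",
    "TaskConfig",
    "AgentParams",
    "TrialRecord",
    "BlockData",
    "BoostContractError",
    "softmax_choice_prob",
    "q_update",
    "apply_social_boost",
    "simulate_block",
    "simulate_session",
]

CONDITIONS = ("control", "observation", "advice")

#: Box bounds of the six free parameters used for sampling and fitting.
PARAM_BOUNDS = {
    "alpha": (0.05, 0.95),
    "beta": (0.1, 50.0),
    "qboost_advice": (0.0, 1.0),
    "qboost_observation": (0.0, 1.0),
    "bboost_advice": (0.1, 50.0),
    "bboost_observation": (0.1, 50.0),
}

#: Canonical ordering of the free parameters in vectors (fitting, reports).
PARAM_ORDER = (
    "alpha",
    "beta",
    "qboost_advice",
    "qboost_observation",
    "bboost_advice",
    "bboost_observation",
)


class BoostContractError(RuntimeError):
    """The one-time social boost was applied where it must not be."""


@dataclass(frozen=True)
class TaskConfig:
    """Generative parameters of the fishing task.

    Defaults reproduce the study design: good-lake mean 5.5 fish/trial,
    bad-lake mean 4 fish/trial, common sd 1.7, 15 trials per block, social
    cue after the feedback of trial 4.

    ``q_init`` is the initial Q-value of both lakes (the midpoint of the two
    generative means by default, which avoids a first-trial novelty
    asymmetry while staying on the reward scale).  ``q_max_mode`` selects
    the ceiling used by the value boost: ``"observed_max"`` (the largest
    reward received so far in the block — the maximum a learner could have
    represented from experience) or ``"fixed"`` (use ``q_max_fixed``).
    """

    mean_good: float = 5.5
    mean_bad: float = 4.0
    reward_sd: float = 1.7
    n_trials: int = 15
    cue_after_trial: int = 4
    q_init: float = 4.75
    q_max_mode: str = "observed_max"
    q_max_fixed: float = 7.2
    round_rewards: bool = False  # display convenience only

    def __post_init__(self) -> None:
        if not self.mean_good > self.mean_bad:
            raise ValueError("mean_good must exceed mean_bad")
        if not self.reward_sd > 0:
            raise ValueError("reward_sd must be positive")
        if not 1 <= self.cue_after_trial < self.n_trials:
            raise ValueError("cue_after_trial must lie in [1, n_trials)")
        if self.q_max_mode not in ("observed_max", "fixed"):
            raise ValueError("q_max_mode must be 'observed_max' or 'fixed'")


@dataclass(frozen=True)
class AgentParams:
    """The six free parameters of the agent.

    ``alpha`` is the delta-rule learning rate, ``beta`` the baseline softmax
    precision (inverse temperature).  ``qboost_*`` weight the one-time value
    boost toward the ceiling in each social condition; ``bboost_*`` replace
    ``beta`` after the cue.  ``bboost_*`` default to ``None``, meaning "same
    as beta" (no precision change).
    """

    alpha: float
    beta: float
    qboost_advice: float = 0.0
    qboost_observation: float = 0.0
    bboost_advice: Optional[float] = None
    bboost_observation: Optional[float] = None

    def __post_init__(self) -> None:
        # mathematical domain; the tighter estimation box in PARAM_BOUNDS is
        # enforced where it matters (sampling and fitting), so limiting cases
        # like beta = 0 (uniform choice) remain expressible
        domain = {
            "alpha": (0.0, 1.0),
            "beta": (0.0, PARAM_BOUNDS["beta"][1]),
            "qboost_advice": (0.0, 1.0),
            "qboost_observation": (0.0, 1.0),
            "bboost_advice": (0.0, PARAM_BOUNDS["bboost_advice"][1]),
            "bboost_observation": (0.0, PARAM_BOUNDS["bboost_observation"][1]),
        }
        for name in PARAM_ORDER:
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite")
            lo, hi = domain[name]
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")

    def qboost_for(self, condition: str) -> float:
        return {"advice": self.qboost_advice, "observation": self.qboost_observation}[condition]

    def bboost_for(self, condition: str) -> float:
        value = {"advice": self.bboost_advice, "observation": self.bboost_observation}[condition]
        return self.beta if value is None else value

    def as_vector(self) -> np.ndarray:
        """Parameters in :data:`PARAM_ORDER`; unset bboosts resolve to beta."""
        return np.array(
            [
                self.alpha,
                self.beta,
                self.qboost_advice,
                self.qboost_observation,
                self.bboost_for("advice"),
                self.bboost_for("observation"),
            ]
        )

    @classmethod
    def from_vector(cls, x: Sequence[float]) -> "AgentParams":
        return cls(**dict(zip(PARAM_ORDER, (float(v) for v in x))))


@dataclass
class TrialRecord:
    """One trial: 1-based index, chosen lake (0=A, 1=B), realized reward.

    ``q_a``/``q_b`` are the model Q-values *entering* the trial and are only
    present in simulated data.  ``rt_ms`` is the response time when known.
    """

    trial: int
    choice: int
    reward: float
    rt_ms: Optional[float] = None
    q_a: Optional[float] = None
    q_b: Optional[float] = None

    def __post_init__(self) -> None:
        if self.choice not in (0, 1):
            raise ValueError("choice must be 0 (lake A) or 1 (lake B)")
        if self.trial < 1:
            raise ValueError("trial index is 1-based")


@dataclass
class BlockData:
    """One participant-block: condition, position in session, lakes, trials.

    ``cue_target`` is the lake indicated by social information; it is always
    the good lake in social blocks and ``None`` in control blocks.
    """

    condition: str
    block_order: int
    good_lake: int
    cue_target: Optional[int]
    trials: list[TrialRecord] = field(default_factory=list)
    cue_after_trial: int = 4

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.condition == "control":
            if self.cue_target is not None:
                raise ValueError("control blocks carry no cue_target")
        else:
            if self.cue_target != self.good_lake:
                raise ValueError("social information always indicates the good lake")

    @property
    def is_social(self) -> bool:
        return self.condition != "control"

    def good_choice_indicators(self) -> list[int]:
        return [int(t.choice == self.good_lake) for t in self.trials]


def softmax_choice_prob(q_a: float, q_b: float, beta: float) -> float:
    """Probability of choosing lake A under the softmax rule.

    ``p(A) = exp(beta*q_a) / (exp(beta*q_a) + exp(beta*q_b))``, evaluated in
    the numerically stable logistic form (shift by the max Q before
    exponentiation).  ``beta = 0`` gives exactly 0.5.
    """
    if not (math.isfinite(q_a) and math.isfinite(q_b) and math.isfinite(beta)):
        raise ValueError("softmax inputs must be finite")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    d = beta * (q_a - q_b)
    if d >= 0:
        return 1.0 / (1.0 + math.exp(-d))
    e = math.exp(d)
    return e / (1.0 + e)


def q_update(q_old: float, reward: float, alpha: float) -> float:
    """Delta-rule update: ``q_new = q_old + alpha * (reward - q_old)``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not (math.isfinite(q_old) and math.isfinite(reward)):
        raise ValueError("q_update inputs must be finite")
    return q_old + alpha * (reward - q_old)


def apply_social_boost(
    state: tuple[float, float, float],
    cue_target: int,
    qboost: float,
    bboost: float,
    q_max: float,
    condition: str = "advice",
    already_applied: bool = False,
) -> tuple[float, float, float]:
    """One-time social boost applied to ``state = (q_a, q_b, beta)``.

    The cued lake's Q moves to ``(1 - qboost) * Q_old + qboost * q_max`` (so
    ``qboost = 1`` sets it exactly to the ceiling); the other lake is
    untouched; the precision is replaced by ``bboost`` for the rest of the
    block.  Raises :class:`BoostContractError` when invoked on a control
    block or a second time within a block.
    """
    if condition == "control":
        raise BoostContractError("control blocks are never boosted")
    if already_applied:
        raise BoostContractError("the social boost is applied at most once per block")
    if cue_target not in (0, 1):
        raise ValueError("cue_target must be 0 or 1")
    if not 0.0 <= qboost <= 1.0:
        raise ValueError("qboost must lie in [0, 1]")
    if bboost < 0 or not math.isfinite(bboost):
        raise ValueError("bboost must be finite and non-negative")
    q_a, q_b, _ = state
    if cue_target == 0:
        q_a = (1.0 - qboost) * q_a + qboost * q_max
    else:
        q_b = (1.0 - qboost) * q_b + qboost * q_max
    return (q_a, q_b, bboost)


def _resolve_q_max(config: TaskConfig, rewards_so_far: Sequence[float]) -> float:
    if config.q_max_mode == "fixed":
        return config.q_max_fixed
    if len(rewards_so_far) == 0:
        return config.q_init
    return max(rewards_so_far)


def simulate_block(
    config: TaskConfig,
    params: AgentParams,
    condition: str,
    rng_seed,
    good_lake: Optional[int] = None,
    block_order: int = 1,
) -> BlockData:
    """Simulate one block of the task.

    ``rng_seed`` may be an int or a ``numpy.random.SeedSequence``.  Potential
    yields for *both* lakes are pre-drawn for every trial, so the reward
    stream a block would deliver is fixed by the seed regardless of the
    agent's choices or the condition.  With an identical seed the output is
    bit-identical.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng(rng_seed)
    if good_lake is None:
        good_lake = int(rng.integers(2))
    elif good_lake not in (0, 1):
        raise ValueError("good_lake must be 0 or 1")

    n = config.n_trials
    means = np.where(np.arange(2) == good_lake, config.mean_good, config.mean_bad)
    yields = rng.normal(loc=means, scale=config.reward_sd, size=(n, 2))
    if config.round_rewards:
        yields = np.rint(yields)
    choice_u = rng.random(n)

    social = condition != "control"
    cue_target = good_lake if social else None
    qboost = params.qboost_for(condition) if social else 0.0
    bboost = params.bboost_for(condition) if social else params.beta

    q_a = q_b = config.q_init
    beta = params.beta
    boosted = False
    trials: list[TrialRecord] = []
    rewards: list[float] = []
    for t in range(1, n + 1):
        if social and not boosted and t == config.cue_after_trial + 1:
            q_a, q_b, beta = apply_social_boost(
                (q_a, q_b, beta),
                cue_target,
                qboost,
                bboost,
                _resolve_q_max(config, rewards),
                condition=condition,
            )
            boosted = True
        p_a = softmax_choice_prob(q_a, q_b, beta)
        choice = 0 if choice_u[t - 1] < p_a else 1
        reward = float(yields[t - 1, choice])
        trials.append(
            TrialRecord(trial=t, choice=choice, reward=reward, q_a=q_a, q_b=q_b)
        )
        rewards.append(reward)
        if choice == 0:
            q_a = q_update(q_a, reward, params.alpha)
        else:
            q_b = q_update(q_b, reward, params.alpha)

    return BlockData(
        condition=condition,
        block_order=block_order,
        good_lake=good_lake,
        cue_target=cue_target,
        trials=trials,
        cue_after_trial=config.cue_after_trial,
    )


def simulate_session(
    config: TaskConfig,
    params: AgentParams,
    block_order: Sequence[str],
    rng_seed,
) -> list[BlockData]:
    """Simulate a three-block session (control / observation / advice).

    ``block_order`` must be a permutation of the three condition labels.
    Each block position gets its own sub-seed derived deterministically from
    ``(rng_seed, position)``, so permuting the conditions does not perturb
    the per-position reward streams.
    """
    if sorted(block_order) != sorted(CONDITIONS):
        raise ValueError(f"block_order must be a permutation of {CONDITIONS}")
    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(CONDITIONS))
    return [
        simulate_block(config, params, condition, child, block_order=i + 1)
        for i, (condition, child) in enumerate(zip(block_order, children))
    ]
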