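"""Choice likelihood and per-participant constrained maximum-likelihood fits.

The likelihood is teacher-forced: Q-values are propagated along the
participant's *actual* choice and reward sequence, and each trial
contributes ``-log p(choice_t | Q_t, beta_t)`` under the softmax rule.  In
social blocks the one-time value/precision boost enters the trajectory at
the configured point, so control blocks depend only on ``(alpha, beta)``
while social blocks additionally identify the condition's boost parameters.

Fitting minimizes the summed negative log-likelihood of a participant's
three blocks over the six-parameter box (L-BFGS-B) from several seeded
random starts plus the bounds-box midpoint.  Participants are classified as
*exploiters* (high) in a condition when the fitted post-cue precision is
above 40 — close to the ceiling of 50 — and *explorers* (low) otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .task import (
    CONDITIONS,
    PARAM_BOUNDS,
    PARAM_ORDER,
    AgentParams,
    BlockData,
    TaskConfig,
)

__all__ = [
    "FitSettings",
    "FitResult",
    "BBOOST_HIGH_THRESHOLD",
    "block_nll",
    "session_nll",
    "fit_participant",
    "classify_bboost",
    "cohort_fit",
    "fit_summary",
]

logger = logging.getLogger(__name__)

#: Fitted post-cue precision above this value counts as "high" (ceiling 50).
BBOOST_HIGH_THRESHOLD = 40.0


@dataclass(frozen=True)
class FitSettings:
    """Optimizer configuration for per-participant fits.

    ``n_starts`` seeded random initial points are used in addition to the
    bounds-box midpoint.  ``bounds`` defaults to the study's parameter box.
    ``q_init``/``q_max_mode``/``q_max_fixed`` override the task config when
    set, so fits can probe initial-value assumptions without touching the
    generative config.
    """

    bounds: dict = field(default_factory=lambda: dict(PARAM_BOUNDS))
    n_starts: int = 10
    start_seed: int = 0
    ftol: float = 1e-9
    gtol: float = 1e-7
    maxiter: int = 200
    q_init: Optional[float] = None
    q_max_mode: Optional[str] = None
    q_max_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")

    def resolve_config(self, config: TaskConfig) -> TaskConfig:
        kwargs = {}
        if self.q_init is not None:
            kwargs["q_init"] = self.q_init
        if self.q_max_mode is not None:
            kwargs["q_max_mode"] = self.q_max_mode
        if self.q_max_fixed is not None:
            kwargs["q_max_fixed"] = self.q_max_fixed
        if not kwargs:
            return config
        from dataclasses import replace

        return replace(config, **kwargs)


@dataclass
class FitResult:
    """Per-participant estimates and diagnostics."""

    params_hat: AgentParams
    nll: float
    n_trials_used: int
    n_starts: int
    converged: bool
    bboost_class_advice: str
    bboost_class_observation: str

    @property
    def group4(self) -> str:
        """Four-group partition: none / observation / advice / both."""
        high_a = self.bboost_class_advice == "high"
        high_o = self.bboost_class_observation == "high"
        if high_a and high_o:
            return "both"
        if high_a:
            return "advice"
        if high_o:
            return "observation"
        return "none"


def _block_arrays(block: BlockData, config: TaskConfig):
    """Flatten a block into plain-Python sequences for the fast NLL loop.

    Returns ``(choices, rewards, social, cue_target, boost_pos, q_max_obs)``
    where ``boost_pos`` is the position (0-based, in the surviving ordered
    sequence) *before* which the boost applies, or -1 for control blocks,
    and ``q_max_obs`` is the largest reward observed up to the cue trial
    (falls back to ``q_init`` when every pre-cue trial was excluded).
    """
    if len(block.trials) == 0:
        raise ValueError("cannot evaluate the likelihood of an empty block")
    choices = [t.choice for t in block.trials]
    rewards = [float(t.reward) for t in block.trials]
    social = block.is_social
    cue = block.cue_target if social else -1
    boost_pos = -1
    q_max_obs = config.q_init
    if social:
        boost_pos = len(choices)  # boost may fall after the last surviving trial
        for i, t in enumerate(block.trials):
            if t.trial > config.cue_after_trial:
                boost_pos = i
                break
        pre = [r for t, r in zip(block.trials, rewards) if t.trial <= config.cue_after_trial]
        if pre:
            q_max_obs = max(pre)
    return choices, rewards, social, cue, boost_pos, q_max_obs


def _nll_core(
    choices: Sequence[int],
    rewards: Sequence[float],
    social: bool,
    cue: int,
    boost_pos: int,
    q_max_obs: float,
    alpha: float,
    beta: float,
    qboost: float,
    bboost: float,
    config: TaskConfig,
) -> float:
    # hot loop: plain floats and math.* on purpose (called thousands of
    # times per participant by the optimizer)
    q_a = q_b = config.q_init
    b = beta
    nll = 0.0
    q_max = config.q_max_fixed if config.q_max_mode == "fixed" else q_max_obs
    exp = math.exp
    log1p = math.log1p
    for i, c in enumerate(choices):
        if social and i == boost_pos:
            if cue == 0:
                q_a = (1.0 - qboost) * q_a + qboost * q_max
            else:
                q_b = (1.0 - qboost) * q_b + qboost * q_max
            b = bboost
        d = b * (q_a - q_b)
        z = d if c == 0 else -d  # log-odds of the chosen lake
        if z >= 0:
            nll += log1p(exp(-z))
        else:
            nll += log1p(exp(z)) - z
        r = rewards[i]
        if c == 0:
            q_a += alpha * (r - q_a)
        else:
            q_b += alpha * (r - q_b)
    return nll


def block_nll(block: BlockData, params: AgentParams, config: TaskConfig) -> float:
    """Teacher-forced negative log-likelihood of one block, in nats."""
    choices, rewards, social, cue, boost_pos, q_max_obs = _block_arrays(block, config)
    condition = block.condition
    qboost = params.qboost_for(condition) if social else 0.0
    bboost = params.bboost_for(condition) if social else params.beta
    return _nll_core(
        choices, rewards, social, cue, boost_pos, q_max_obs,
        params.alpha, params.beta, qboost, bboost, config,
    )


def session_nll(blocks: Sequence[BlockData], params: AgentParams, config: TaskConfig) -> float:
    """Summed NLL over a participant's blocks."""
    return sum(block_nll(b, params, config) for b in blocks)


def classify_bboost(bboost_hat: float) -> str:
    """``"high"`` iff the fitted post-cue precision exceeds 40 (strict)."""
    lo, hi = PARAM_BOUNDS["bboost_advice"]
    if not lo <= bboost_hat <= hi:
        raise ValueError(f"bboost_hat={bboost_hat} outside [{lo}, {hi}]")
    return "high" if bboost_hat > BBOOST_HIGH_THRESHOLD else "low"


def _prepared_objective(blocks: Sequence[BlockData], config: TaskConfig):
    prepared = []
    for block in blocks:
        arrays = _block_arrays(block, config)
        prepared.append((block.condition, arrays))

    def objective(x) -> float:
        alpha, beta, qb_a, qb_o, bb_a, bb_o = (float(v) for v in x)
        total = 0.0
        for condition, (choices, rewards, social, cue, boost_pos, q_max_obs) in prepared:
            if condition == "advice":
                qboost, bboost = qb_a, bb_a
            elif condition == "observation":
                qboost, bboost = qb_o, bb_o
            else:
                qboost, bboost = 0.0, beta
            total += _nll_core(
                choices, rewards, social, cue, boost_pos, q_max_obs,
                alpha, beta, qboost, bboost, config,
            )
        return total

    return objective


#: Absolute NLL slack (nats) within which a boundary value of a post-cue
#: precision is considered likelihood-equivalent to the interior estimate.
_PLATEAU_TOL = 1e-9


def _polish_bboost_plateau(objective, x, nll, lo, hi):
    """Resolve flat post-cue-precision ridges to their boundary supremum.

    When every post-cue choice picks the currently better lake, the block
    likelihood is monotone (non-increasing NLL) in the post-cue precision
    and numerically flat over a wide interval, so a quasi-Newton stop point
    inside the plateau is arbitrary.  The maximum-likelihood value is then
    the boundary; for each post-cue precision we therefore move the estimate
    to whichever bound is likelihood-equivalent (within ``_PLATEAU_TOL``)
    or strictly better, preferring the boundary on ties.
    """
    x = np.array(x, dtype=float)
    for dim in (PARAM_ORDER.index("bboost_advice"), PARAM_ORDER.index("bboost_observation")):
        for bound in (hi[dim], lo[dim]):
            if x[dim] == bound:
                continue
            candidate = x.copy()
            candidate[dim] = bound
            f = objective(candidate)
            if f <= nll + _PLATEAU_TOL:
                x, nll = candidate, min(f, nll)
                break
    return x, nll


def fit_participant(
    blocks: Sequence[BlockData],
    settings: FitSettings,
    config: TaskConfig,
) -> FitResult:
    """Joint constrained MLE of the six parameters over three blocks.

    The participant must contribute exactly one block per condition (trials
    already filtered by the response-time rule).  All starts failing is
    reported through ``converged=False``, never as an exception.
    """
    conditions = sorted(b.condition for b in blocks)
    if conditions != sorted(CONDITIONS):
        raise ValueError("fit_participant expects exactly one block per condition")
    config = settings.resolve_config(config)
    objective = _prepared_objective(blocks, config)
    bounds = [settings.bounds[name] for name in PARAM_ORDER]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    rng = np.random.default_rng(settings.start_seed)
    starts = [0.5 * (lo + hi)]
    starts.extend(lo + rng.random((settings.n_starts, len(bounds))) * (hi - lo))

    best_x = starts[0]
    best_nll = math.inf
    converged = False
    for x0 in starts:
        try:
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "ftol": settings.ftol,
                    "gtol": settings.gtol,
                    "maxiter": settings.maxiter,
                },
            )
        except Exception:  # pragma: no cover - defensive: optimizer blow-up
            logger.warning("optimizer start failed", exc_info=True)
            continue
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best_x = np.clip(res.x, lo, hi)
            converged = converged or bool(res.success)
        elif res.success:
            converged = True

    if not math.isfinite(best_nll):
        best_nll = float(objective(best_x))

    best_x, best_nll = _polish_bboost_plateau(objective, best_x, best_nll, lo, hi)
    params_hat = AgentParams.from_vector(best_x)
    return FitResult(
        params_hat=params_hat,
        nll=best_nll,
        n_trials_used=sum(len(b.trials) for b in blocks),
        n_starts=len(starts),
        converged=converged,
        bboost_class_advice=classify_bboost(params_hat.bboost_for("advice")),
        bboost_class_observation=classify_bboost(params_hat.bboost_for("observation")),
    )


def cohort_fit(
    participants: dict[str, Sequence[BlockData]] | Sequence[tuple[str, Sequence[BlockData]]],
    settings: FitSettings,
    config: TaskConfig,
) -> pd.DataFrame:
    """Fit every participant independently; one row per participant.

    Participants missing a condition are skipped with a logged warning.
    Start seeds are derived per participant from ``settings.start_seed`` so
    the whole table is reproducible yet starts differ across participants.
    """
    if isinstance(participants, dict):
        items = list(participants.items())
    else:
        items = list(participants)
    rows = []
    ss = np.random.SeedSequence(settings.start_seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(max(len(items), 1))]
    from dataclasses import replace as _replace

    for (pid, blocks), seed in zip(items, seeds):
        have = sorted(b.condition for b in blocks)
        if have != sorted(CONDITIONS):
            logger.warning("participant %s skipped: conditions %s", pid, have)
            continue
        fit = fit_participant(blocks, _replace(settings, start_seed=seed), config)
        p = fit.params_hat
        rows.append(
            {
                "participant_id": pid,
                "alpha_hat": p.alpha,
                "beta_hat": p.beta,
                "qboost_adv_hat": p.qboost_advice,
                "qboost_obs_hat": p.qboost_observation,
                "bboost_adv_hat": p.bboost_for("advice"),
                "bboost_obs_hat": p.bboost_for("observation"),
                "nll": fit.nll,
                "n_trials_used": fit.n_trials_used,
                "converged": fit.converged,
                "class_adv": fit.bboost_class_advice,
                "class_obs": fit.bboost_class_observation,
                "group4": fit.group4,
            }
        )
    columns = [
        "participant_id", "alpha_hat", "beta_hat", "qboost_adv_hat",
        "qboost_obs_hat", "bboost_adv_hat", "bboost_obs_hat", "nll",
        "n_trials_used", "converged", "class_adv", "class_obs", "group4",
    ]
    return pd.DataFrame(rows, columns=columns)


def fit_summary(fits: pd.DataFrame) -> dict:
    """High-precision shares per condition and the four-group partition."""
    n = len(fits)
    if n == 0:
        return {
            "n": 0,
            "share_high_advice": math.nan,
            "share_high_observation": math.nan,
            "share_high_both": math.nan,
            "group4_counts": {},
        }
    high_a = (fits["class_adv"] == "high")
    high_o = (fits["class_obs"] == "high")
    return {
        "n": n,
        "share_high_advice": float(high_a.mean()),
        "share_high_observation": float(high_o.mean()),
        "share_high_both": float((high_a & high_o).mean()),
        "group4_counts": fits["group4"].value_counts().to_dict(),
    }
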