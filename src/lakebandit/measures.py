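"""Preregistered behavioral measures, trial exclusion, bonus, and summaries.

Per block the package computes:

* ``immediate_follow`` — did trial 5 (the first choice after the social cue)
  pick the good lake;
* ``longterm_perf`` — proportion of good-lake choices over trials 6-15;
* ``convergence_trial`` — first trial opening a run of three consecutive
  good-lake choices (censored as ``n_trials + 1`` when no run exists);
* ``u_value`` — normalized Shannon entropy of the binary choice sequence, a
  stochasticity index in [0, 1].

Trials slower than 20 s are excluded before scoring.  The bonus is 20 pence
per full 50 fish caught, capped at 180 pence.  ``summarize_cohort`` gives
per-condition means with percentile-bootstrap CIs and paired condition
differences, standing in for full mixed-effects inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import BlockData, TaskConfig, TrialRecord

__all__ = [
    "BlockMeasures",
    "filter_long_trials",
    "immediate_follow",
    "longterm_performance",
    "convergence_trial",
    "u_value",
    "bonus_pence",
    "block_measures",
    "cohort_measures",
    "summarize_cohort",
]

RT_THRESHOLD_S = 20.0
MEASURE_COLUMNS = ("immediate_follow", "longterm_perf", "convergence_trial", "u_value")


@dataclass
class BlockMeasures:
    """The four behavioral measures plus exclusion bookkeeping for one block."""

    immediate_follow: Optional[int]
    longterm_perf: Optional[float]
    convergence_trial: int
    converged: bool
    u_value: float
    n_excluded: int


def filter_long_trials(
    trials: Sequence[TrialRecord], threshold_s: float = RT_THRESHOLD_S
) -> tuple[list[TrialRecord], int]:
    """Drop trials slower than ``threshold_s`` seconds; keep unknown RTs.

    Order is preserved.  Negative response times are rejected.
    """
    kept = []
    removed = 0
    for t in trials:
        if t.rt_ms is not None and t.rt_ms < 0:
            raise ValueError("response times cannot be negative")
        if t.rt_ms is not None and t.rt_ms > threshold_s * 1000.0:
            removed += 1
        else:
            kept.append(t)
    return kept, removed


def immediate_follow(block: BlockData) -> Optional[int]:
    """1 iff the first post-cue choice (trial 5) picked the good lake.

    Returns ``None`` when that trial was excluded — absence of evidence, not
    a failure to follow.
    """
    target_trial = block.cue_after_trial + 1
    for t in block.trials:
        if t.trial == target_trial:
            return int(t.choice == block.good_lake)
    return None


def longterm_performance(block: BlockData, n_trials: int = 15) -> Optional[float]:
    """Mean good-lake choice over surviving trials 6 .. ``n_trials``."""
    start = block.cue_after_trial + 2
    indicators = [
        int(t.choice == block.good_lake)
        for t in block.trials
        if start <= t.trial <= n_trials
    ]
    if not indicators:
        return None
    return float(np.mean(indicators))


def convergence_trial(
    block: BlockData, run_length: int = 3, n_trials: int = 15
) -> tuple[int, bool]:
    """First trial starting ``run_length`` consecutive good choices.

    Runs are scored on the surviving-trial sequence in original order; the
    returned index is the trial number of the run's first trial.  When no
    run exists the censor code ``n_trials + 1`` is returned with
    ``converged=False``.
    """
    good = block.good_choice_indicators()
    trial_ids = [t.trial for t in block.trials]
    streak = 0
    for i, g in enumerate(good):
        streak = streak + 1 if g else 0
        if streak >= run_length:
            return trial_ids[i - run_length + 1], True
    return n_trials + 1, False


def u_value(block: BlockData, window: str = "all") -> float:
    """Normalized entropy of the block's choice proportions, in [0, 1].

    With ``p`` the proportion of scored trials choosing lake A,
    ``U = -[p log2 p + (1-p) log2 (1-p)]`` (with ``0 log 0 = 0``).  A
    constant sequence scores 0; an even split scores 1.  ``window`` is
    ``"all"`` (default, all 15 trials) or ``"post_cue"`` (trials after the
    social cue only).
    """
    if window == "all":
        choices = [t.choice for t in block.trials]
    elif window == "post_cue":
        choices = [t.choice for t in block.trials if t.trial > block.cue_after_trial]
    else:
        raise ValueError("window must be 'all' or 'post_cue'")
    if not choices:
        raise ValueError("u_value needs at least one surviving trial")
    p = sum(1 for c in choices if c == 0) / len(choices)
    return _binary_entropy(p)


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * math.log2(p) + (1.0 - p) * math.log2(1.0 - p))


def bonus_pence(
    total_fish: float,
    pence_per_block: int = 20,
    fish_per_block: int = 50,
    cap_pence: int = 180,
    pro_rata: bool = False,
) -> float:
    """Performance bonus: 20 pence per full 50 fish, capped at 180 pence.

    ``pro_rata=True`` pays fractional blocks instead of flooring.
    """
    if total_fish < 0:
        raise ValueError("total_fish cannot be negative")
    blocks = total_fish / fish_per_block
    if not pro_rata:
        blocks = math.floor(blocks)
    return min(blocks * pence_per_block, cap_pence)


def block_measures(
    block: BlockData,
    config: TaskConfig,
    threshold_s: float = RT_THRESHOLD_S,
) -> BlockMeasures:
    """Apply the RT filter, then score all four measures for one block."""
    kept, removed = filter_long_trials(block.trials, threshold_s)
    filtered = BlockData(
        condition=block.condition,
        block_order=block.block_order,
        good_lake=block.good_lake,
        cue_target=block.cue_target,
        trials=kept,
        cue_after_trial=block.cue_after_trial,
    )
    conv, flag = convergence_trial(filtered, n_trials=config.n_trials)
    return BlockMeasures(
        immediate_follow=immediate_follow(filtered),
        longterm_perf=longterm_performance(filtered, n_trials=config.n_trials),
        convergence_trial=conv,
        converged=flag,
        u_value=u_value(filtered),
        n_excluded=removed,
    )


def cohort_measures(
    participants: dict[str, Sequence[BlockData]],
    config: TaskConfig,
    threshold_s: float = RT_THRESHOLD_S,
) -> pd.DataFrame:
    """Measures table: one row per participant-block, plus the session bonus."""
    rows = []
    for pid, blocks in participants.items():
        total_fish = sum(t.reward for b in blocks for t in b.trials)
        bonus = bonus_pence(total_fish)
        for block in blocks:
            m = block_measures(block, config, threshold_s)
            rows.append(
                {
                    "participant_id": pid,
                    "condition": block.condition,
                    "immediate_follow": m.immediate_follow,
                    "longterm_perf": m.longterm_perf,
                    "convergence_trial": m.convergence_trial,
                    "converged_flag": m.converged,
                    "u_value": m.u_value,
                    "n_excluded": m.n_excluded,
                    "bonus_pence": bonus,
                }
            )
    return pd.DataFrame(rows)


def summarize_cohort(
    measures: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    columns: Sequence[str] = MEASURE_COLUMNS,
) -> pd.DataFrame:
    """Per-condition means with percentile-bootstrap 95% CIs.

    Resampling is over participants (rows stay paired within participant),
    so paired condition differences are also reported, as rows with
    ``condition`` like ``"advice-control"``.
    """
    if measures["participant_id"].nunique() < 2:
        raise ValueError("summarize_cohort needs at least 2 participants")
    rng = np.random.default_rng(seed)
    rows = []
    for col in columns:
        wide = measures.pivot_table(
            index="participant_id", columns="condition", values=col, aggfunc="mean"
        )
        conditions = list(wide.columns)
        data = wide.to_numpy(dtype=float)
        n = data.shape[0]
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = np.nanmean(data[idx, :], axis=1)  # (n_boot, n_conditions)
        for j, cond in enumerate(conditions):
            rows.append(
                {
                    "measure": col,
                    "condition": cond,
                    "mean": float(np.nanmean(data[:, j])),
                    "ci_lo": float(np.quantile(boot_means[:, j], 0.025)),
                    "ci_hi": float(np.quantile(boot_means[:, j], 0.975)),
                }
            )
        for a in range(len(conditions)):
            for b in range(a + 1, len(conditions)):
                diff = data[:, b] - data[:, a]
                boot_diff = boot_means[:, b] - boot_means[:, a]
                rows.append(
                    {
                        "measure": col,
                        "condition": f"{conditions[b]}-{conditions[a]}",
                        "mean": float(np.nanmean(diff)),
                        "ci_lo": float(np.quantile(boot_diff, 0.025)),
                        "ci_hi": float(np.quantile(boot_diff, 0.975)),
                    }
                )
    return pd.DataFrame(rows)
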