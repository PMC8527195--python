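"""Simulation experiments: boost sweeps and mixed explorer/exploiter populations.

Three experiments probe how the two social mechanisms shape learning curves
(per-trial proportion of simulated agents choosing the good lake):

* a **qboost sweep** isolates the immediate, decaying effect of the one-time
  value boost;
* a **bboost sweep** isolates the lasting effect of replacing the softmax
  precision after the cue;
* **mixture runs** simulate populations containing a proportion of
  high-precision "exploiter" agents among low-precision "explorers", whose
  aggregate curve can mimic an intermediate homogeneous precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import AgentParams, TaskConfig, simulate_block

__all__ = ["SweepSpec", "LearningCurve", "run_sweep", "run_mixture", "curves_to_frame"]

_SWEEPABLE = ("qboost", "bboost", "mixture_ratio")


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: which parameter, its grid, population size and base agent."""

    parameter: str
    grid: tuple
    base: AgentParams
    condition: str = "advice"
    n_agents: int = 2000
    seed: int = 0
    params_high: Optional[AgentParams] = None  # mixture sweeps only
    params_low: Optional[AgentParams] = None

    def __post_init__(self) -> None:
        if self.parameter not in _SWEEPABLE:
            raise ValueError(f"parameter must be one of {_SWEEPABLE}")
        if len(self.grid) == 0:
            raise ValueError("grid must be non-empty")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.parameter == "mixture_ratio":
            if not all(0.0 <= v <= 1.0 for v in self.grid):
                raise ValueError("mixture ratios must lie in [0, 1]")
            if self.params_high is None or self.params_low is None:
                raise ValueError("mixture sweeps need params_high and params_low")


@dataclass
class LearningCurve:
    """Per-trial proportion of agents choosing the good lake at one grid value."""

    grid_value: float
    p_good: np.ndarray
    n_agents: int
    n_high: Optional[int] = None  # realized exploiter count in mixture runs

    def __post_init__(self) -> None:
        self.p_good = np.asarray(self.p_good, dtype=float)
        if np.any((self.p_good < 0) | (self.p_good > 1)):
            raise ValueError("choice proportions must lie in [0, 1]")

    def mean_longterm(self, config: TaskConfig) -> float:
        """Mean performance on the post-cue long-term window (trials 6-15)."""
        return float(self.p_good[config.cue_after_trial + 1 :].mean())


def _with_value(base: AgentParams, parameter: str, condition: str, value: float) -> AgentParams:
    field = f"{parameter}_{condition}"
    return replace(base, **{field: value})


def _simulate_population(
    config: TaskConfig,
    params_of_agent,
    condition: str,
    n_agents: int,
    seed_seq: np.random.SeedSequence,
) -> np.ndarray:
    children = seed_seq.spawn(n_agents)
    good = np.zeros(config.n_trials)
    for i, child in enumerate(children):
        block = simulate_block(config, params_of_agent(i), condition, child)
        good += block.good_choice_indicators()
    return good / n_agents


def run_sweep(spec: SweepSpec, config: TaskConfig) -> list[LearningCurve]:
    """Simulate ``n_agents`` blocks per grid value and aggregate learning curves.

    Deterministic under ``spec.seed``; each grid value uses its own sub-seed
    so enlarging the grid never perturbs existing curves.
    """
    root = np.random.SeedSequence(spec.seed)
    grid_seeds = root.spawn(len(spec.grid))
    curves = []
    for value, ss in zip(spec.grid, grid_seeds):
        if spec.parameter == "mixture_ratio":
            curves.append(
                run_mixture(
                    value, spec.n_agents, spec.params_high, spec.params_low,
                    config, ss, condition=spec.condition,
                )
            )
            continue
        params = _with_value(spec.base, spec.parameter, spec.condition, value)
        p_good = _simulate_population(config, lambda i: params, spec.condition, spec.n_agents, ss)
        curves.append(LearningCurve(grid_value=float(value), p_good=p_good, n_agents=spec.n_agents))
    return curves


def run_mixture(
    ratio_high: float,
    n_agents: int,
    params_high: AgentParams,
    params_low: AgentParams,
    config: TaskConfig,
    seed,
    condition: str = "advice",
) -> LearningCurve:
    """Aggregate curve of a population that is exploiter with prob ``ratio_high``."""
    if not 0.0 <= ratio_high <= 1.0:
        raise ValueError("ratio_high must lie in [0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    assign_ss, sim_ss = ss.spawn(2)
    is_high = np.random.default_rng(assign_ss).random(n_agents) < ratio_high
    p_good = _simulate_population(
        config,
        lambda i: params_high if is_high[i] else params_low,
        condition,
        n_agents,
        sim_ss,
    )
    return LearningCurve(
        grid_value=float(ratio_high),
        p_good=p_good,
        n_agents=n_agents,
        n_high=int(is_high.sum()),
    )


def curves_to_frame(curves: Sequence[LearningCurve]) -> pd.DataFrame:
    """Long-format table: grid_value, trial, p_good, n_agents."""
    rows = []
    for c in curves:
        for t, p in enumerate(c.p_good, start=1):
            rows.append(
                {"grid_value": c.grid_value, "trial": t, "p_good": p, "n_agents": c.n_agents}
            )
    return pd.DataFrame(rows)
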