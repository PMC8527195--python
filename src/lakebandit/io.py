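"""Trial-table CSV read/write, schema validation, and YAML config loading.

The trial CSV is flat (one row per trial) with columns::

    participant_id, condition, block_order, trial, choice, reward, rt_ms,
    good_lake, cue_target, cue_after_trial, paranoia

Missing values (e.g. ``cue_target`` in control blocks) are empty fields.
Floats are serialized with 9 significant digits so written tables
round-trip to the precision needed for likelihood comparisons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec
from .likelihood import FitSettings
from .task import CONDITIONS, BlockData, TaskConfig, TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "ValidationReport",
    "write_trials",
    "read_trials",
    "sessions_from_frame",
    "validate_trials",
    "load_task_config",
    "load_cohort_spec",
    "load_fit_settings",
]

TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "block_order",
    "trial",
    "choice",
    "reward",
    "rt_ms",
    "good_lake",
    "cue_target",
    "cue_after_trial",
    "paranoia",
]

FLOAT_FORMAT = "%.9g"


def write_trials(trials: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the trial table as UTF-8 CSV with empty fields for missing."""
    out = trials.reindex(columns=TRIAL_COLUMNS)
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read a trial CSV; ``cue_target``/``rt_ms`` stay nullable."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    return df


def sessions_from_frame(
    trials: pd.DataFrame, config: Optional[TaskConfig] = None
) -> dict[str, list[BlockData]]:
    """Rebuild per-participant :class:`BlockData` lists from a flat table."""
    sessions: dict[str, list[BlockData]] = {}
    grouped = trials.sort_values(["participant_id", "block_order", "trial"]).groupby(
        ["participant_id", "condition"], sort=False
    )
    for (pid, condition), g in grouped:
        cue_target = g["cue_target"].iloc[0]
        cue_target = None if pd.isna(cue_target) else int(cue_target)
        records = [
            TrialRecord(
                trial=int(r.trial),
                choice=int(r.choice),
                reward=float(r.reward),
                rt_ms=None if pd.isna(r.rt_ms) else float(r.rt_ms),
            )
            for r in g.itertuples()
        ]
        block = BlockData(
            condition=condition,
            block_order=int(g["block_order"].iloc[0]),
            good_lake=int(g["good_lake"].iloc[0]),
            cue_target=cue_target,
            trials=records,
            cue_after_trial=int(g["cue_after_trial"].iloc[0]),
        )
        sessions.setdefault(str(pid), []).append(block)
    for blocks in sessions.values():
        blocks.sort(key=lambda b: b.block_order)
    return sessions


@dataclass
class ValidationReport:
    n_rows: int
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_trials(trials: Union[pd.DataFrame, str, Path], n_trials: int = 15) -> ValidationReport:
    """Schema and domain checks on a trial table.

    Verifies column presence, value domains (choice in {0,1}, trial in
    [1, n_trials], known condition labels), the social-cue consistency rule
    (the cue always indicates the good lake; control blocks carry no cue),
    and duplicate (participant, condition, trial) keys.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = read_trials(trials)
    errors: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        return ValidationReport(n_rows=len(trials), errors=[f"missing columns: {missing}"])

    bad_choice = ~trials["choice"].isin([0, 1])
    if bad_choice.any():
        errors.append(f"{int(bad_choice.sum())} rows with choice outside {{0,1}}")
    bad_trial = (trials["trial"] < 1) | (trials["trial"] > n_trials)
    if bad_trial.any():
        errors.append(f"{int(bad_trial.sum())} rows with trial outside [1, {n_trials}]")
    bad_cond = ~trials["condition"].isin(CONDITIONS)
    if bad_cond.any():
        errors.append(f"{int(bad_cond.sum())} rows with unknown condition label")

    social = trials["condition"].isin(["advice", "observation"])
    cue = trials["cue_target"]
    bad_cue = social & (cue.isna() | (cue != trials["good_lake"]))
    if bad_cue.any():
        errors.append(
            f"{int(bad_cue.sum())} social rows where cue_target != good_lake "
            "(social information must always indicate the good lake)"
        )
    control_cue = (~social) & cue.notna()
    if control_cue.any():
        errors.append(f"{int(control_cue.sum())} control rows carrying a cue_target")

    dup = trials.duplicated(subset=["participant_id", "condition", "trial"])
    if dup.any():
        errors.append(f"{int(dup.sum())} duplicate (participant, condition, trial) keys")
    return ValidationReport(n_rows=len(trials), errors=errors)


def _load_yaml(path: Union[str, Path]) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return data


def _from_mapping(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    return cls(**data)


def load_task_config(path: Union[str, Path]) -> TaskConfig:
    return _from_mapping(TaskConfig, _load_yaml(path), str(path))


def load_cohort_spec(path: Union[str, Path]) -> CohortSpec:
    return _from_mapping(CohortSpec, _load_yaml(path), str(path))


def load_fit_settings(path: Union[str, Path]) -> FitSettings:
    data = _load_yaml(path)
    if "bounds" in data:
        data["bounds"] = {k: tuple(v) for k, v in data["bounds"].items()}
    return _from_mapping(FitSettings, data, str(path))
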