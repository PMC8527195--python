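"""End-to-end pipeline (generate -> validate -> stats -> fit) and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from . import __version__
from .cohort import CohortSpec, generate_cohort, recovery_experiment
from .io import (
    FLOAT_FORMAT,
    sessions_from_frame,
    validate_trials,
    write_trials,
)
from .likelihood import FitSettings, cohort_fit, fit_summary
from .measures import cohort_measures, summarize_cohort
from .task import TaskConfig

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunManifest:
    """Record tying a run's seeds and configuration to its outputs."""

    command: str
    config_hash: str
    seeds: dict
    inputs: dict
    outputs: dict
    package_version: str
    timestamp: str

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _config_hash(*objs) -> str:
    payload = json.dumps(
        [dataclasses.asdict(o) for o in objs], sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    outdir,
    spec: Optional[CohortSpec] = None,
    config: Optional[TaskConfig] = None,
    fit_settings: Optional[FitSettings] = None,
    n_boot: int = 2000,
    run_recovery: bool = False,
    quiet: bool = False,
) -> RunManifest:
    """Generate a cohort, validate, score measures, fit, and write artifacts.

    Writes ``trials.csv``, ``truth.csv``, ``measures.csv``, ``summary.csv``,
    ``fits.csv`` (and optionally ``recovery.json``) plus ``manifest.json``
    under ``outdir``.  A failing stage aborts with the stage named.
    """
    spec = spec or CohortSpec()
    config = config or TaskConfig()
    fit_settings = fit_settings or FitSettings()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    level = logging.WARNING if quiet else logging.INFO
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("generate")
        trials, truth = generate_cohort(spec, config)
        write_trials(trials, outdir / "trials.csv")
        truth.to_csv(outdir / "truth.csv", index=False, float_format=FLOAT_FORMAT)
    except Exception as exc:
        raise PipelineError(f"generate failed: {exc}") from exc

    try:
        stage("validate")
        report = validate_trials(trials, n_trials=config.n_trials)
        if not report.ok:
            raise ValueError("; ".join(report.errors))
    except Exception as exc:
        raise PipelineError(f"validate failed: {exc}") from exc

    try:
        stage("stats")
        sessions = sessions_from_frame(trials, config)
        measures = cohort_measures(sessions, config)
        measures.to_csv(outdir / "measures.csv", index=False, float_format=FLOAT_FORMAT)
        summary = summarize_cohort(measures, n_boot=n_boot, seed=spec.seed)
        summary.to_csv(outdir / "summary.csv", index=False, float_format=FLOAT_FORMAT)
    except Exception as exc:
        raise PipelineError(f"stats failed: {exc}") from exc

    try:
        stage("fit")
        # fits are run on the RT-filtered sessions
        from .measures import filter_long_trials

        for blocks in sessions.values():
            for block in blocks:
                block.trials, _ = filter_long_trials(block.trials)
        fits = cohort_fit(sessions, fit_settings, config)
        fits.to_csv(outdir / "fits.csv", index=False, float_format=FLOAT_FORMAT)
        with open(outdir / "fit_summary.json", "w", encoding="utf-8") as fh:
            json.dump(fit_summary(fits), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise PipelineError(f"fit failed: {exc}") from exc

    outputs = {
        "trials": str(outdir / "trials.csv"),
        "truth": str(outdir / "truth.csv"),
        "measures": str(outdir / "measures.csv"),
        "summary": str(outdir / "summary.csv"),
        "fits": str(outdir / "fits.csv"),
        "fit_summary": str(outdir / "fit_summary.json"),
    }
    if run_recovery:
        try:
            stage("recover")
            report = recovery_experiment(spec, config, fit_settings)
            with open(outdir / "recovery.json", "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
            outputs["recovery"] = str(outdir / "recovery.json")
        except Exception as exc:
            raise PipelineError(f"recover failed: {exc}") from exc

    manifest = RunManifest(
        command="pipeline",
        config_hash=_config_hash(spec, config, fit_settings),
        seeds={"cohort": spec.seed, "fit_starts": fit_settings.start_seed},
        inputs={},
        outputs=outputs,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(outdir / "manifest.json")
    return manifest
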