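#!/usr/bin/env python
"""Fit the six-parameter model to a synthetic cohort and classify phenotypes.

Generates 120 participants with the default generator (exploiter shares
0.39 advice / 0.34 observation / 0.18 joint), fits each by multi-start
L-BFGS-B, and partitions the cohort by fitted post-cue precision (> 40 =
exploiter) into the four groups: none / observation only / advice only /
both.

Writes results/fits.csv and results/fit_groups.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lakebandit import CohortSpec, FitSettings, TaskConfig, generate_sessions
from lakebandit.likelihood import cohort_fit, fit_summary
from lakebandit.measures import filter_long_trials

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = TaskConfig()
    spec = CohortSpec(n_participants=120, seed=31)
    sessions, truth = generate_sessions(spec, config)
    for blocks in sessions.values():
        for block in blocks:
            block.trials, _ = filter_long_trials(block.trials)

    fits = cohort_fit(sessions, FitSettings(n_starts=10, start_seed=32), config)
    RESULTS.mkdir(exist_ok=True)
    fits.to_csv(RESULTS / "fits.csv", index=False, float_format="%.6g")

    summary = fit_summary(fits)
    groups = pd.DataFrame(
        [{"group": g, "n": n} for g, n in sorted(summary["group4_counts"].items())]
    )
    groups.to_csv(RESULTS / "fit_groups.csv", index=False)

    true_adv = truth["high_advice"].mean()
    true_obs = truth["high_observation"].mean()
    print(f"Fitted {summary['n']} participants (10 random starts + midpoint each).")
    print(f"High post-cue precision share, advice:      "
          f"estimated {summary['share_high_advice']:.2f} vs generated {true_adv:.2f}")
    print(f"High post-cue precision share, observation: "
          f"estimated {summary['share_high_observation']:.2f} vs generated {true_obs:.2f}")
    print(f"High in both conditions:                    "
          f"estimated {summary['share_high_both']:.2f}")
    print("\nFour-group partition of the cohort:")
    print(groups.to_string(index=False))


if __name__ == "__main__":
    main()
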