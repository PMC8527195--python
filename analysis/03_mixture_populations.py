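#!/usr/bin/env python
"""Mixed explorer/exploiter populations reproduce intermediate group curves.

A population in which only a fraction of agents exploit the cue long-term
(post-cue precision at the ceiling of 50) produces an aggregate learning
curve lying between the homogeneous extremes and rising monotonically with
the exploiter share — the alternative reading of a moderate group-level
social-information effect.

Writes results/mixture_curves.csv.
"""

import sys
from dataclasses import replace
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lakebandit import AgentParams, SweepSpec, TaskConfig, curves_to_frame, run_sweep

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = TaskConfig()
    base = AgentParams(alpha=0.2, beta=2.0, qboost_advice=1.0, qboost_observation=1.0)
    spec = SweepSpec(
        parameter="mixture_ratio",
        grid=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
        base=base,
        params_high=replace(base, bboost_advice=50.0),
        params_low=replace(base, bboost_advice=0.4),
        n_agents=2000,
        seed=13,
    )
    curves = run_sweep(spec, config)
    RESULTS.mkdir(exist_ok=True)
    curves_to_frame(curves).to_csv(RESULTS / "mixture_curves.csv", index=False, float_format="%.4f")

    print("Mixture populations, mean P(good lake) on trials 6-15:")
    for c in curves:
        print(f"  exploiter share {c.grid_value:3.1f} (realized {c.n_high:4d}/2000): "
              f"{c.mean_longterm(config):.3f}")
    perf = [c.mean_longterm(config) for c in curves]
    assert all(b >= a - 0.04 for a, b in zip(perf, perf[1:]))
    print("  -> long-term performance rises monotonically with the exploiter share;")
    print("     a ~40% share already yields a clearly elevated group curve.")


if __name__ == "__main__":
    main()
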