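# lakebandit

Simulation, likelihood fitting, and behavioral measurement for a
two-armed-bandit social-learning task ("which of two lakes should I fish
from?"), built for computational cognitive modelling of how advice and
observed choices shape reinforcement learning — and for anyone who needs a
fully synthetic, ground-truthed test bed for softmax Q-learning pipelines.

## The task and model

Participants choose between two lakes for 15 trials per block; yields are
Gaussian (good lake mean 5.5 fish, bad lake 4, sd 1.7). Each session has
three blocks — control, observation, advice — and in the two social blocks
a single always-accurate cue indicates the good lake after trial 4.

Learning is delta-rule Q-learning with softmax choice,

    Q(t+1) = Q(t) + α · (reward(t) − Q(t)),      P(A) = e^{βQ_A} / (e^{βQ_A} + e^{βQ_B}),

and social information acts once, between trials 4 and 5:

* `Qboost` moves the cued lake's value toward a ceiling (the largest reward
  seen so far) — an *immediate* effect that decays as learning resumes;
* `βboost` replaces the softmax precision for the rest of the block — a
  *lasting* shift from exploration to exploitation of the cued option.

Each participant is fit by constrained multi-start L-BFGS-B over
{α, β, Qboost_advice, Qboost_obs, βboost_advice, βboost_obs}, and is
classified per condition as an **exploiter** when the fitted post-cue
precision exceeds 40 (ceiling 50), else an **explorer**. A synthetic-cohort
generator with a bimodal βboost population, a right-skewed paranoia
covariate linked to advice-taking, and realistic response times drives
every analysis closed-loop. The preregistered behavioral measures (trial-5
cue-following, long-term performance on trials 6–15, convergence trial,
U-value choice stochasticity, the 20 s trial exclusion and the bonus rule)
are implemented with bootstrap group summaries.

## Worked example

```python
from lakebandit import (AgentParams, CohortSpec, FitSettings, TaskConfig,
                        generate_sessions)
from lakebandit.likelihood import cohort_fit, fit_summary

config = TaskConfig()                      # the task as run: 5.5/4.0, sd 1.7, cue after 4
spec = CohortSpec(n_participants=120, seed=31)
sessions, truth = generate_sessions(spec, config)
fits = cohort_fit(sessions, FitSettings(n_starts=10, start_seed=32), config)
print(fit_summary(fits))
```

This generates 120 synthetic participants and fits each one; the analysis
driver `analysis/05_fit_cohort.py` runs exactly this and prints:

```
Fitted 120 participants (10 random starts + midpoint each).
High post-cue precision share, advice:      estimated 0.42 vs generated 0.42
High post-cue precision share, observation: estimated 0.28 vs generated 0.28
High in both conditions:                    estimated 0.13
```

i.e. the fitted exploiter shares recover the generated mixture. The other
numbered drivers under `analysis/` tell the rest of the story: `02` shows
the value boost's immediate-but-decaying effect (trial-5 gap 0.254 shrinks
to 0.029 by trial 15) against the precision boost's sustained near-ceiling
effect (0.965 mean on trials 6–15); `03` shows mixture populations rising
monotonically with the exploiter share; `04` scores the behavioral
measures on an effect-calibrated cohort (long-term performance 0.779
advice / 0.749 observation / 0.699 control with separated bootstrap CIs).

A CLI mirrors the library (`lakebandit generate|validate|stats|fit|sweep|
mixture|recover|pipeline`); every run is seeded and the pipeline writes a
manifest tying seeds to outputs.

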