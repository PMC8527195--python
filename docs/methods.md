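# Methods

## The task

Each participant-block is a two-armed bandit framed as choosing which of two
lakes to fish from, 15 trials long. Yields are Gaussian: the good lake pays
5.5 fish per trial on average, the bad lake 4, both with standard deviation
1.7, so single outcomes are only weakly diagnostic of which lake is better.
A session is three blocks — control, observation, advice — with the order
counterbalanced across participants (all six permutations cycled evenly).
In the two social conditions a single, always-accurate cue indicating the
good lake appears after the feedback of trial 4; the control block has no
cue. A performance bonus pays 20 pence per full 50 fish caught, capped at
180 pence.

## The model

Choice is modelled as softmax over learned Q-values with delta-rule
updating:

    Q_chosen(t+1) = Q_chosen(t) + alpha * (reward(t) - Q_chosen(t))
    P(choose A)   = exp(beta * Q_A) / (exp(beta * Q_A) + exp(beta * Q_B))

Social information acts through two one-time changes, applied between the
feedback of the cue trial and the next choice, and never in control blocks:

* **value boost** — the cued lake's Q moves a fraction `qboost` of the way
  toward a ceiling `q_max`; `qboost = 1` sets it exactly to the ceiling.
* **precision boost** — the softmax precision `beta` is *replaced* by
  `bboost` for every remaining trial of the block (replacement, not
  addition, because the parameter *sets* the post-cue precision; the
  replacement persists to the end of the block, which is what produces a
  lasting effect from a one-time event).

Each condition has its own pair, giving six free parameters per
participant: `alpha` in [0.05, 0.95], `beta` in [0.1, 50], `qboost_advice`
and `qboost_observation` in [0, 1], `bboost_advice` and
`bboost_observation` in [0.1, 50].

Two quantities the model needs are not pinned down by the design and are
exposed as configuration:

* **Initial Q-values** default to 4.75, the midpoint of the two generative
  means. This keeps initial values on the reward scale and avoids an
  artificial first-trial asymmetry. (Zero initialisation would make the
  first rewards look like large positive surprises for both lakes.)
* **The boost ceiling `q_max`** defaults to the largest reward the agent
  has received so far in the current block (`observed_max`) — the highest
  value a learner could have represented from its own experience. A
  `fixed` mode (constant ceiling, default 7.2 ≈ good mean + 1 sd) is
  available for sensitivity analyses.

## Likelihood and fitting

The likelihood is teacher-forced: Q-values are propagated along the
participant's actual choice/reward sequence and each trial contributes
`-log p(choice_t)` under the softmax with the precision in force at that
trial. Control blocks therefore depend only on `(alpha, beta)`; each social
block additionally identifies its condition's `(qboost, bboost)`. The six
parameters are estimated jointly over the participant's three blocks
(one parameter set per participant), by L-BFGS-B within the box bounds from
10 seeded random starts plus the bounds-box midpoint. Trials slower than
20 s are excluded before fitting. Probabilities are evaluated in log-sum-exp
form; the per-trial term is `log(1 + exp(-z))` with `z` the log-odds of the
chosen lake, so `beta = 0` gives exactly `log 2` per trial and extreme
precisions cannot overflow.

**Plateau polish.** When every post-cue choice picks the currently
higher-valued lake, the block NLL is monotone non-increasing in `bboost`
and numerically flat beyond moderate values, so a finite-difference
quasi-Newton stop point inside that plateau is arbitrary (it simply echoes
the start). The maximum-likelihood value is then the boundary. After the
multi-start search, each post-cue precision is therefore moved to a box
boundary whenever that boundary's NLL is better or equal within 1e-9 nats.
Without this step a large fraction of genuinely at-ceiling agents are
returned mid-plateau, at a value determined by the random starts rather
than by the data.

Participants are classified per condition as **exploiters** (`high`) when
the fitted post-cue precision exceeds 40 — close to the ceiling of 50 —
and **explorers** (`low`) otherwise; ties at exactly 40 are `low`. The
four-group partition (none / observation / advice / both) follows from the
two labels. Estimates at the ceiling are reported as-is; mass at the bound
is informative (it is the exploiter mode), not a fitting artifact.

The summed NLL is reported in nats per participant-session. No comparison
is made to any per-block or differently signed log-likelihood convention.

## Synthetic cohort generator

The generator produces full study-shaped datasets (n participants × 3
blocks × 15 trials) with ground-truth parameters, so the whole analysis
runs closed-loop without human data. Defaults, per agent:

* `alpha ~ 0.05 + 0.9 * Beta(2, 2)` — symmetric around 0.5;
* `beta ~ Lognormal(median 8.6, sigma 0.8)`, clipped to bounds;
* `qboost`: with probability 0.65 (advice) / 0.50 (observation) exactly 1,
  otherwise a Beta(2, 1) tail — a point mass at the "maximum level" with a
  left tail;
* exploiter labels: `high` with probability 0.39 (advice) and 0.34
  (observation), overlapping so that 0.18 of agents are high in both.
  The two labels are drawn from a shared Gaussian latent whose correlation
  is solved numerically so all three shares hold simultaneously;
* `bboost`: 50 (the ceiling) for exploiters; for explorers
  `Lognormal(median 0.4, sigma 0.4)` clipped to [0.1, 2];
* paranoia: an integer score on [0, 40] (the persecution subscale's range)
  from a discretised Gamma(2, 4.5) — right-skewed, most mass at low scores.
  Two linkages, both acting per score point relative to the population
  mean: the advice point-mass-at-1 weight shrinks on the logit scale
  (slope −0.05), and the log-odds of being an exploiter shrink (slope
  −0.04, common to both conditions). Intercepts are solved against the
  paranoia distribution so the population shares stay at their targets;
* response times: `Lognormal(median 1.5 s, sigma 0.5)`, with a 0.003
  probability per trial of a slow outlier drawn uniformly above the 20 s
  exclusion threshold.

**Why the explorer precision is low.** The explorer mode is calibrated so
the two phenotypes are behaviorally distinct at 15 trials per block: with
the cued lake boosted to the observed maximum, Q-gaps post-cue are around
1.5–2.5 fish, so only a post-cue precision of order 1 or less produces the
variable, exploratory choice pattern that separates explorers from
exploiters in the likelihood. With a higher explorer mode (median 1.5),
explorers frequently produce all-argmax post-cue sequences and ~40% of
them fit at the ceiling, destroying classification recovery; at median 0.4
the false-high rate is ~4–5% per condition and the false-low rate ~0–1%,
so generated mixture shares are recovered within binomial error at n=500.
These values describe the synthetic population, not an estimate of any
human population.

**Study-effect configuration.** Model agents with the default baseline
precision learn the control block more cleanly than humans did, so the
plain defaults do not reproduce the study's group-level profile. The
`CohortSpec.study_effect()` configuration (baseline precision median 0.8;
exploiter shares 0.55 advice / 0.42 observation / 0.28 joint) was
calibrated once so the generated cohort shows the study-shaped profile:
long-term performance ordered advice (~0.77) > observation (~0.75) >
control (~0.70), immediate cue-following highest for advice, and choice
stochasticity lowest for advice. It is used by the behavioral-summary
analyses; the plain defaults are used everywhere recovery of the fitted
shares is the point.

**What the generator does not emulate.** Real participants are not softmax
Q-learners: the generator has no choice perseveration, no lapses, no
learning across blocks, no RT–choice coupling (fast exploiters / slow
deliberation), and its explorer/exploiter split is exactly binary rather
than merely bimodal. Passing closed-loop tests therefore demonstrates that
the estimation and measurement pipeline is correct and well-calibrated
under the model's own assumptions — not that the model is true of people.

## Behavioral measures

Per block, after removing trials slower than 20 s (kept when RT is
unknown):

* **immediate follow** — indicator that trial 5 (first post-cue choice)
  picked the good lake; missing (not 0) when trial 5 was excluded;
* **long-term performance** — mean good-lake choice over surviving trials
  6–15;
* **convergence trial** — first trial opening three consecutive good-lake
  choices, scored on the surviving sequence in order; censored as
  `n_trials + 1` with a flag when no run exists (kept, not dropped, so
  cohort summaries remain computable);
* **U-value** — normalized first-order Shannon entropy of the binary
  choice sequence: with `p` the proportion choosing lake A,
  `U = -[p log2 p + (1-p) log2 (1-p)]`, with `0 log 0 = 0`. Scored over
  all 15 trials by default (a `post_cue` window is available); this is an
  interpretation of the U-value as a stochasticity index, since only the
  index's name and range are fixed by convention.

`summarize_cohort` reports per-condition means with percentile-bootstrap
95% CIs resampled over participants (rows stay paired within participant),
plus paired condition differences. This deliberately replaces mixed-effects
regressions with Type III Wald tests and estimated marginal means/trends,
which are out of scope; directions of effects are instead verified on
synthetic cohorts.

## Numerical and design choices

* All randomness flows from `numpy` `SeedSequence` trees: sessions spawn
  per-block child seeds keyed by block *position*, and both potential
  yields (for both lakes) and choice thresholds are pre-drawn per trial, so
  permuting the condition order leaves each position's reward stream
  untouched.
* Reward values are kept continuous (Gaussian draws); an integer-rounding
  switch exists for display only.
* CSV numbers are serialized with 9 significant digits; round-tripped
  tables reproduce likelihood values to ~1e-6 nats.
* Multi-start count (10 + midpoint) was chosen for a bounded 6-D landscape
  with plateaus at the precision ceiling; fits are deterministic given the
  start seed, and per-participant start seeds are spawned from the cohort
  fit seed.
* Simulation experiments default to 2000 agents per grid point (Monte-
  Carlo SE of a proportion ≤ ~0.011). The test suite uses 500–600 agents
  for sweep checks, 50–80 participants for recovery unit checks, and one
  500-participant closed-loop run; the recovery analyses in `analysis/`
  use 120–150 participants. These sizes are the package's choices for
  routine runs; all thresholds were fixed from calibration runs before the
  tests were frozen.

## Known limitations

* The baseline precision `beta` is weakly identified from 45 trials (MAE
  ~15–20 in closed-loop recovery); the learning rate and boost parameters
  recover far better. This is a property of short softmax bandit blocks,
  not of the optimizer.
* `qboost` is only identified when pre-cue experience leaves the cued
  lake's Q clearly below the ceiling; when trial 1–4 rewards are high the
  boost has little room to act and the estimate shrinks toward the prior
  landscape's plateau.
* With `observed_max` as ceiling, the boost can (rarely) be a *downgrade*
  target when all pre-cue rewards were poor; this is intended behavior of
  the experience-based ceiling.
* The classification threshold (>40) is fixed by convention; agents with
  true `bboost` between ~10 and 40 would be near-unclassifiable at this
  block length, which is why the generator's explorer mode sits well below.
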