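# Methods

## The dual-process model

All three estimators target the same two latent quantities. Recollection is
modelled as an all-or-none threshold process: with probability R the subject
retrieves the study episode, which guarantees an "old" decision (and the top
confidence rating, or a Remember attribution, or the veto of a recombined
pair). Familiarity is a continuous strength signal: studied items draw from
N(δ, 1), unstudied items from N(0, 1), and a decision arises from comparing
the draw to one or more criteria. Under these assumptions the three tasks'
estimators are consistent for (R, δ) — which is exactly what the simulator
generates, making parameter recovery a fair end-to-end check.

### Signal-detection core

Every rate is corrected as (x + 0.5)/(n + 1) before the probit transform.
The correction is applied uniformly — in the d′/c computation of every task
and inside the process-dissociation and Remember/Know/Guess index formulas.
Uniformity is a deliberate choice: it keeps every rate strictly inside
(0, 1), makes R = 1 (and the division by 1 − R) unreachable, and removes
any special-casing of floor/ceiling subjects, at the price of a small and
sample-size-dependent shrinkage toward 0.5 that affects both groups
equally. The correction can be switched off in the process-dissociation
estimator for sensitivity analysis.

### Confidence-ROC fitting

The 2×6 confidence table is fit by multinomial maximum likelihood rather
than least squares on ROC points: ML is statistically efficient, handles
zero cells, and yields a log-likelihood for model comparison. A
sum-of-squared-error fit on the five ROC points is available
(`method="sse"`) as a cross-check. Numerical choices:

- Parameterization: logit(R); d_f bounded in [0, 6]; criteria as first
  criterion plus log-increments, which enforces strict ordering without
  constraints.
- Predicted cell probabilities are floored at 1e-12 inside the log; the
  analytic gradient zeroes the contribution of floored cells so objective
  and gradient stay consistent.
- Optimizer: L-BFGS-B with analytic gradients, objective tolerance 1e-8;
  one data-driven start (criteria from probit-transformed cumulative
  false-alarm rates, R from the top-category hit/false-alarm excess, d_f
  from the yes/no collapse d′) plus up to 10 seeded random restarts.
  Restarting stops once the best objective has been reproduced twice within
  a relative 1e-6, which typically happens after two or three restarts;
  `n_restarts_used` records the number actually run.
- A table with all responses of both item types in a single category is
  returned flagged non-identifiable instead of raising.
- Recollection maps to the single top confidence category; this standard
  assumption is not configurable.
- Encoding depth (deep/shallow) is carried through the trial records but
  collapsed in scoring; the headline outputs are one index set per subject.

### Process dissociation

R = p(included) − p(excluded), F = p(excluded)/(1 − R), with the corrected
rates by default. The task's own d′/c contrast intact pairs against new
pairs (pure old/new discrimination); pooling new with recombined pairs is
available via `fa_class="pooled"`. Recombined pairs are deliberately left
out of the default false-alarm class because the process-dissociation
equations already consume them.

### Remember/Know/Guess

The default estimator is the independence Remember-Know form given in the
module docstring. Two recognised ambiguities are exposed as options rather
than silently resolved: a "literal" variant computes the corrected yes-rate
difference multiplied by the Remember share of target yeses, and
`drop_guesses=True` removes Guess trials entirely instead of counting them
as familiarity-driven yeses. Defaults: independence form, guesses counted
as familiarity. The familiarity ratio can touch 1.0 exactly when every
non-Remember trial of a class is a familiarity yes; it is clamped back to
the open interval the Snodgrass correction guarantees
(±0.5/(n + 1)) so the probit stays finite.

## Group statistics

- Mann-Whitney U: exact enumeration when n1·n2 ≤ 400 and the pooled sample
  has no ties (scipy's exact method), otherwise the normal approximation
  with midrank tie correction and no continuity correction. Two-sided
  throughout, α = 0.05.
- Permutation tests: difference in group means by default (medians and the
  rank sum are options); all C(n1+n2, n1) splits enumerated when there are
  at most 50,000 (the study's 12-vs-25 uses Monte Carlo, the 7-vs-5
  subgroup contrast is always exhaustive). Monte Carlo p-values use the
  add-one estimator (1 + #extreme)/(1 + n_perm) and are bit-reproducible
  given a seed.
- Effect size A (stochastic superiority) by exhaustive pair counting, ties
  half-weighted: O(n1·n2) is trivial at study scale.
- Spearman rho: midrank Pearson correlation; exact permutation p for
  n ≤ 8, t approximation otherwise; constant rankings are flagged
  undefined, not raised.
- Holm: step-down with enforced monotonicity, capped at 1. The family is
  the three per-task comparisons of one index (and, separately, the three
  averaged-z comparisons); the grouping is configurable in the pipeline
  because no single family definition is canonical.
- z-summaries use the control mean and SD (ddof = 1) per task × index;
  subjects missing a task are excluded from summaries and logged; a zero
  control SD raises an error naming the offending index.

## The simulator

`simulate_cohort` emulates the full study: 12 patients (7 labelled dMTT,
5 iMTT) and 25 controls; per subject 180 confidence-ROC trials
(120 targets, 60 distractors), 120 pair trials (40/40/40), and 120
Remember/Know/Guess trials (60/60). Latents per subject: ρ (recollection
probability), δ (familiarity strength), five confidence criteria centred
on δ/2 with fixed offsets (−1.6 … 1.6) plus N(0, 0.1) jitter, a yes/no
criterion δ/2 + N(0, 0.15), and a guess rate ~N(0.10, 0.05) clipped to
[0, 0.4].

Default group configurations: controls ρ = 0.55 (SD 0.12), δ = 1.30
(SD 0.25); patients ρ = 0.15 (SD 0.08) with δ matched to controls — a
severe, selective recollection deficit consistent with the large
recollection effect sizes this design is meant to detect. These defaults
were calibrated once, with the package's replication bands (patient
deficit flagged in ≥90% of cohorts for z_R and z_d′, ≤30% for z_F over
200 cohorts) as acceptance constants. When `subgroup_effects=True`, dMTT
patients draw from ρ = 0.12 / δ = 0.95 and iMTT from ρ = 0.25 / δ = 1.30,
reproducing the pattern where the damaged-MTT subgroup also loses
familiarity; by default all patients share the recollection-only deficit.

Recombined-pair familiarity defaults to the full δ (`delta_assoc_frac=1`,
components were studied); it can be attenuated toward 0. No
encoding-depth or word-valence effects are generated.

What the simulator does **not** emulate: item-level variation in
memorability (word frequency, length), criterion drift over the test list,
response omissions or lapses, and any dependence between the three tasks
beyond the shared latents. Passing parameter-recovery and replication
tests therefore shows the estimators are correct under the dual-process
assumptions, not that those assumptions hold for any particular real
dataset.

## Problem sizes

Consistency checks run at ~10,000 items per response class, where ±0.05
recovery tolerances comfortably exceed sampling noise. The replication
sweep uses 200 cohorts at the study design; type-I calibration uses 1,000
null replicates with 999 Monte Carlo permutations each. The recovery
report contrasts the study-scale design with a 10× design over 20
replicate subjects per scale.

## Known limitations

- The ROC fit assumes equal-variance familiarity; unequal-variance and
  mixture alternatives are out of scope, so a real dataset generated by
  those processes will bias R upward.
- With only 60 distractors, the familiarity index of the
  Remember/Know/Guess task is the noisiest of the three (visible in the
  recovery report's RMSE).
- The independence assumptions of the process-dissociation and
  Remember/Know/Guess corrections are taken as given; redundancy-model
  variants are not implemented.
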