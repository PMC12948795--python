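# Methods note

This note records, in one place, the exact conventions `chronocog`
implements: the measurement rules, the generative model behind the
synthetic cohorts, the estimators, and the simulation experiments used to
validate them. Everything here is testable, and tested.

## Study design

A cohort (default *n* = 75, ages 18–30) completes a 13-item morningness
questionnaire (CMQ) once, wears a wrist accelerometer for 7 consecutive
days, and performs two task blocks (XNA1, 17 trials; XNA2, 27 trials) at
two sessions per testing day (nominally 09:00 and 21:00) on three
alternating days — six sessions per participant.

## Chronotype

Each CMQ item maps a selected option to a point value; ten items carry
1–4 points and three carry 1–5, so the total is bounded in [13, 55],
higher = earlier chronotype. The shipped key
(`src/chronocog/data/cmq_key.json`) is a synthetic stand-in with exactly
this structure and can be replaced by any licensed key with the same
schema; all scoring logic reads the key rather than hard-coding points.

Quintile groups are formed on the ascending score: cut points are the
20/40/60/80th percentiles (linear interpolation), and a participant's
group index is the number of cut points *strictly below* their score.
Tied scores therefore always share a group, falling to the lower one.
Groups are labelled, late to early:
`late, late_intermediate, neutral, early_intermediate, early`.

## Actigraphy

The unit of observation is the 60-s epoch vector magnitude (Euclidean
norm of triaxial counts), held on a regular time grid with missing epochs
as explicit NaN.

* **Non-wear.** Any maximal run of ≥ 60 consecutive zero-or-missing
  minutes, plus every missing epoch. Wear fraction = 1 − non-wear
  fraction of the grid. Participants with wear fraction strictly below
  0.90 are excluded; exactly 0.90 is retained.
* **Rolling AUC.** The trailing 60-minute sum of epoch values over the
  half-open window (t − 60 min, t], indexed by window end t. A window
  containing any missing epoch is undefined (NaN). With 60-s epochs the
  discrete AUC is numerically the plain sum of the 60 epoch values.
* **Daily peak time.** Per calendar day (windows bucketed by the local
  midnight of their *end* timestamp), the clock hour of the maximum
  rolling AUC; ties go to the earliest window; days with fewer than half
  of their 1440 nominal windows observed are skipped.
* **Mean peak time.** The circular mean of the daily peaks: hours map to
  angles (h·2π/24), the unit vectors are averaged, and the resultant maps
  back to [0, 24). If the resultant length is below 1e−9 the mean is
  undefined and the code refuses rather than returning an arbitrary
  value; an arithmetic mean is available for sensitivity analysis.
* **Total AUC.** The sum of all observed epochs over the week, computed
  only for wear-included participants.
* **Prior-hour activity.** For a session at time t, the sum over
  (t − 60 min, t] with t truncated down to the nearest epoch boundary;
  NaN if any epoch in that window is missing or the window extends before
  the recording.

## Cognition

Per session and task block:

* **RT validity.** Trials with RT outside [125, 5000] ms are discarded;
  values exactly at either bound are retained.
* **Errors.** Counted over *all* trials, before the validity filter, so
  anticipations and lapses still count against engagement.
* **Session summaries.** Mean RT over correct, valid trials (undefined,
  with a warning, if none survive); error count; a caffeine flag for
  ≥ 200 mg in the prior hour; time of day in fractional hours.
* **Engagement.** Sessions with ≥ 8 errors (XNA1) or ≥ 10 (XNA2) are
  flagged excluded with reason "low engagement" and dropped from
  modelling.
* **Normality gate.** Before an RT model is fitted, a Shapiro–Wilk test
  at α = 0.05 decides whether a Box-Cox transform is applied; λ is chosen
  by profile likelihood over a grid from −5 to 5 in steps of 0.01. When
  the transform is applied, fitted coefficients live on the transformed
  scale (recovery experiments fit untransformed so estimates stay on the
  generative millisecond scale).

## Generative model

* **Cohort.** Age ~ truncated Normal(25, 7) on [18, 30]; sex female with
  probability 0.57; latent chronotype uniform on [13, 55]; a per-person
  random intercept u ~ Normal(0, 100 ms); caffeine propensity uniform on
  [0, 0.5].
* **Activity.** A cosinor (mesor 1500, amplitude 1200 with lognormal
  person-level variation, clipped at zero) whose acrophase is linear in
  chronotype — 15 h at the scale midpoint (34) with slope −0.1 h/point,
  so the earliest types peak ≈ 2 h before the latest — plus
  Poisson-timed activity bouts (rate 1.5/day, magnitude 1000) placed by a
  von Mises distribution (κ = 2) around the personal acrophase,
  half-normal epoch noise (sd 300), and 90-min non-wear gaps inserted
  with probability 0.05 per day.
* **Questionnaire.** Item selections are allocated so the sheet's total
  equals the (rounded) latent chronotype exactly; the round trip through
  the scorer is asserted at generation time.
* **Sessions.** Session start = nominal time + Normal(0, 20 min) jitter
  + a lateness term of 1 min per point of (55 − chronotype), clamped to
  [00:30, 23:30] — later types systematically start later.
* **Reaction times.** A shifted lognormal: RT = 125 ms + exp(Normal(log
  (LP − 125), σ)), where LP is the linear predictor built from the
  generative fixed effects (defaults: intercept 1195.21, time of day
  −15.65 ms/h, chronotype −13.39 ms/point, interaction +0.54, age +7.39,
  male +12.15, caffeine +29.68, prior-hour activity −3e−05) plus the
  person's random intercept. The log-scale σ is **constant across
  sessions**, computed once from the residual sd (150 ms) at a reference
  predictor. This matters: if σ were instead recomputed per session as
  residual_sd/(LP − 125), the lognormal mean inflation factor exp(σ²/2)
  would vary with LP, bending E[RT] away from linearity and biasing the
  fitted interaction away from its generative value. With constant σ,
  E[RT] = 125 + k·(LP − 125) for a global constant k ≈ 1.016, so fitted
  fixed effects target the generative coefficients (up to that uniform
  inflation, which is well inside estimation noise at study scale).
* **Errors and contamination.** Per-trial error probability is
  logit-linear in the same predictors; 2% of trials are replaced by
  contaminants (80% anticipations uniform on [50, 120] ms, 20% lapses
  uniform on [5001, 8000] ms) that the validity filter is designed to
  catch.
* **Determinism.** Every stochastic stage draws from
  `np.random.default_rng([seed, stage, index])`, so datasets are
  reproducible to the byte (CSV writers use fixed float formats).

## Estimation

* **Group comparisons.** One-way ANOVA on 7-day total AUC and mean peak
  time by chronotype group: F and p from the standard decomposition,
  partial η² = SS_between/(SS_between + SS_within), and pairwise
  post-hocs as pooled-variance t tests (MS_within, df_within) with
  Bonferroni correction over all pairs.
* **Mixed models.** `statsmodels` MixedLM, REML, random intercept per
  participant, fixed effects: intercept, time of day (h), chronotype
  score, chronotype × time, age, sex, caffeine flag, prior-hour activity.
  Wald z intervals and p-values are used for all fixed effects, which
  guarantees the internal consistency "95% CI excludes 0 ⟺ p < 0.05".
  Rank-deficient designs are refused with the offending columns named;
  a near-zero random-intercept variance sets a `singular` flag.
* **Parameter recovery.** 200 independent replicates of
  simulate → clean → assemble → fit at study scale; per coefficient:
  mean estimate, bias, empirical sd, 95% CI coverage, rejection rate.
  Acceptance requires the interaction's mean estimate within ±0.1 of
  0.54 and coverage in [0.90, 0.98].
* **Type-I error.** 500 replicates with the interaction set to zero;
  the interaction's rejection rate at α = 0.05 must lie in [0.03, 0.07].
  Because the positive interaction is what keeps the linear predictor
  above the 125-ms shift for early chronotypes in evening sessions,
  the null configuration also raises the generative intercept
  (1195.21 → 1700 ms); this changes only the baseline, not the
  hypothesis under test (`simulate.null_interaction_config`).
* **Power planning.** Required sample size for a one-way repeated-
  measures ANOVA from the noncentral F distribution with noncentrality
  λ = N·m·f²/(1 + (m − 1)ρ) for m repeated measures with correlation ρ,
  searching the smallest N meeting the target power. α, power and ρ are
  explicit arguments — the answer is meaningless without them stated.
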