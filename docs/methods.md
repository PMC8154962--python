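# Methods

## Setting and estimand

The package studies a prognostic question: given three binary bedside
findings — insensitivity to a 10 g monofilament, any absent pedal pulse,
and a history of foot ulcer or lower-extremity amputation — what is a
diabetic patient's probability of developing a foot ulcer within 2 years?
Development pools individual-participant data (IPD) from four cohort
studies (two UK community cohorts and two secondary-care foot clinics,
8255 complete cases, 430 events in the source data); validation uses a
fifth, register-based cohort.  The deliverable is an integer clinical
prediction rule (scores 0–4) with an absolute risk attached to each score.

## Predictor harmonization

Source studies recorded examinations at different granularity, so coding is
defined on the raw fields and is deliberately asymmetric in its treatment
of missingness ("any"-detection):

* monofilament: 1 if insensate at **any** tested site; 0 if the filament was
  felt at every observed site (at least one observed); missing only when no
  site was observed.  A single insensate site is decisive even when other
  sites are unobserved.  A stricter variant (missing unless all sites
  observed) is available by flag; the permissive rule is the default because
  the coding keys on "insensate anywhere".  The number of sites is not
  fixed.
* pulses: exactly four entries; 1 if any is absent, 0 if all four are
  present, missing if none is absent but any is unobserved.
* history: three-valued OR of prior ulcer and prior amputation (a missing
  component can only hide a 1, so 0-with-missing is missing).

These rules are monotone in the 1-direction: resolving a missing input can
never turn a coded 1 into a 0.  Analysis is complete-case only; the source
cohorts are 97–98% complete and the generator injects missingness
completely at random, so complete-case filtering is unbiased here by
construction.

## Synthetic cohorts

The generator reproduces the study conditions rather than any individual
patient: per-study complete-data sizes (6478, 1175, 360, 242; validation
3324), predictor prevalences and 2-year outcome rates as published for each
cohort.  Defaults:

* predictors independent Bernoulli at the study prevalences.  Only marginal
  prevalences are published, so independence is the default; a
  Gaussian-copula hook (`predictor_corr`) generates equicorrelated
  predictors with preserved margins when a joint structure is wanted.
* outcomes either at the study's marginal rate (used when checking the
  generator against the published per-study rates) or from the pooled
  logistic model (intercept logit(0.022); coefficients 1.11, 0.70, 1.95 for
  monofilament, pulses, history) with a study-level intercept drawn once
  per cohort from N(0, σ_u²).
* σ_u defaults to 0.3 on the log-odds scale.  The source analysis never
  reports its between-study variance; 0.3 (odds multiplied by ~1.35 for a
  1-SD study) is a moderate, realistic heterogeneity for cohorts spanning
  community and secondary care, and it is a stand-in, not an inferred
  value.
* missingness: MCAR per analysis field (monofilament, pulses, history as a
  unit, outcome), so the complete-case retention is (1−r)⁴ in expectation.
* the combined history flag is drawn first (its prevalence is what is
  published) and then split, ulcer-dominant, with 20% of positives also
  flagged as amputations.  The split is cosmetic: analysis uses the
  combined flag only.

The generator does **not** emulate: correlation between predictors and
age/sex/diabetes-duration (demographics are not in the risk model),
informative missingness, time-to-event structure, or death as a competing
risk.  Passing tests therefore demonstrate the statistical machinery, not
the clinical transportability of the rule.

## Model development

The prognostic model is ordinary pooled logistic regression, all three
predictors forced in, fitted by IRLS to a relative log-likelihood tolerance
of 1e-10 (max 100 iterations; non-convergence raises, never a silent
result).  Wald 95% CIs on the log-odds scale are exponentiated for odds
ratios.  Degenerate inputs (no events, constant predictor, separation) are
errors naming the offending predictor where identifiable.

Sample-size adequacy is checked with a bootstrap uniform shrinkage factor:
refit on each resample (default 500, seeded), take the calibration slope of
the resample model's linear predictor on the original data, and average.
Resamples with non-finite refits are dropped and counted; more than 20%
dropped is an error.  The deviance-based heuristic (χ²−df)/χ² is reported
as a cross-check.  The exact bootstrap recipe is a standard choice among
several reasonable ones.

Conversion to the rule rounds each raw coefficient to the nearest integer
(ties away from zero).  Scaling by a reference coefficient before rounding
— the other textbook route — gives the same 1/1/2 weights for these
coefficients; plain rounding is the default because it is the simplest rule
that reproduces the published weighting.  A weight of 0 triggers a warning.

## Population-average per-score risks

The rule's risk table must hold for an *average* study, not the particular
mix of cohorts, so the score-only model is a logistic regression in the
integer score with a normal study-level random intercept:

    logit P(Y=1 | score=k, study j) = α + γk + u_j,   u_j ~ N(0, σ_u²)

fitted by maximizing the marginal likelihood with adaptive Gauss–Hermite
quadrature (per-study mode + curvature rescaling of 15 Hermite nodes;
L-BFGS-B over (α, γ, σ_u) with σ_u bounded below; single-study data reduce
to ordinary logistic regression with σ_u = 0).  The population-average risk
at score k marginalizes the conditional probability:

    p_k = ∫ expit(α + γk + u) φ(u; σ_u) du          (40-node quadrature)

The 95% CI applies the same marginalization to the Wald endpoints of
α + γk; a delta-method interval is available by flag.  The analytic
attenuation approximation expit(η/√(1+0.346σ_u²)) is provided as a
documented alternative; its worst-case deviation from quadrature is ≈0.006
absolute probability near σ_u = 1 (it is much closer for σ_u ≤ 0.6).
Because expit is concave above 0.5 and convex below, marginalization pulls
risks toward 0.5 relative to the conditional value at the same linear
predictor (Jensen attenuation); the tests check this directly.

With only four studies the maximum-likelihood σ̂_u is very noisy and can
collapse to the boundary 0; this is expected behaviour of a 4-cluster
random-intercept fit, not a defect, and the fit then coincides with the
pooled model.

## Validation

* Discrimination: tie-corrected rank C-statistic (exact over all
  event×non-event pairs), variance by the DeLong placement decomposition —
  chosen over bootstrap for determinism (a seeded bootstrap CI remains
  available for the C-statistic by resampling externally).
* Calibration: slope = coefficient of the rule's linear predictor
  (α + γ·score — raw integer scores carry no probability scale and are
  refused) in a logistic refit on the validation outcomes; calibration-in-
  the-large = intercept of a refit with that linear predictor as fixed
  offset.  Wald CIs.
* Grouped calibration: per-score observed proportions with exact
  Clopper–Pearson 95% CIs (group counts at the highest scores are small, so
  asymptotic intervals would undercover), against the table's predicted
  risks.
* ROC points: one per threshold between distinct score values plus anchors;
  the trapezoidal area equals the tie-corrected C-statistic to 1e-12, and
  the suite asserts that identity on random instances.

## Decision analysis

Net benefit at threshold probability p_t is TP/n − FP/n·p_t/(1−p_t);
treat-none is 0, treat-all is π − (1−π)·p_t/(1−p_t).  The decision curve
treats records with predicted risk ≥ p_t (closed bound, so a cut placed
exactly at a table risk includes that score) over a default grid 0.005 to
0.30 in steps of 0.005.

The referral recommendation is the smallest score whose table risk, used as
a fixed treat/don't-treat cut, has net benefit ≥ treat-all and ≥ 0 at every
grid threshold within a clinically plausible range, default **3–10%**.
That default is fixed by the algebra of the problem rather than tuning: a
cut's net benefit is linear in the threshold odds, so the score-1 cut
(sensitivity ≈ 0.79, treated fraction ≈ 0.44 under the published table and
development score mix) stays positive only up to p_t ≈ 0.12, while the
upper bound must exceed the ~6% event prevalence so that treat-all (the
score-0 cut) is rejected where its net benefit goes negative.  Within 3–10%
the score-1 cut dominates both references, and the recommendation
reproduces the published "refer at score ≥ 1 (risk ≈ 6%)".  When no cut
dominates — e.g. a register whose baseline risk drifted well below the
table, or a flat table with γ = 0 — the result is an explicit
no-recommendation value, not an exception.  No cost weighting beyond the
odds weighting intrinsic to net benefit is applied.

## Problem sizes and determinism

Simulation-based checks use the study-condition sizes: development-scale
fits at n = 8255, validation registers at n = 3324 or 20,000,
parameter-recovery and CI-coverage loops at 200 replicates, Monte-Carlo
oracles at 10⁶ draws.  All randomness flows from explicit integer seeds
(one root seed per pipeline run, spawned per stage), and identical config +
seed reproduces byte-identical JSON/CSV artifacts.

## Known limitations

* Predictors are simulated independently by default; real neuropathy,
  arterial disease and ulcer history co-occur, so simulated discrimination
  can differ from the published validation (C ≈ 0.70 under independence vs
  0.83 reported on the real register, where clustering of risk factors
  sharpens the score's separation).
* The between-study SD default is a stand-in; per-score CIs under few
  clusters are Wald-based and can be optimistic.
* No recalibration/updating of the rule for new settings is implemented;
  the validation module reports metrics only.
* Outcome timing is a fixed 2-year binary; deaths before 2 years are not
  modelled as competing risks.
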