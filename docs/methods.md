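# Methods

This note records the models the package implements, the calibration of the
synthetic-trial generator, and the numerical and design choices made where
the published arm-level summaries leave the generating law open.

## Wave clock and horizon

Waves are anchored at baseline = 0, the 9-week assessment at 63/365.25 ≈
0.1725 y, and the later follow-ups 6 months and 2 years *after the 9-week
assessment*, i.e. 0.6725 y and 2.1725 y. The analysis horizon is therefore
2.1725 years. This clock is the one consistent with the published mean
QALYs: the trapezoid of the published arm-level utility means over these
times reproduces the published per-arm QALY means to within 0.01, which a
plain 2.0-year horizon does not.

## Change model

For each clinical outcome the estimand is the between-arm difference in
change from baseline at each follow-up. The model is a linear mixed model
with a saturated arm×wave fixed-effect structure (each arm retains its own
baseline mean — baseline equality is *not* imposed), a subject-level random
intercept and no random slopes, fitted by maximum likelihood (not REML, so
likelihood-ratio comparisons across fixed-effect specifications remain
valid) on all available rows, which is the standard likelihood-based MAR
treatment. With complete data the estimates coincide with differences of
raw arm-wave mean changes; the tests use that identity as an oracle at
1e-8. Cluster-robust (sandwich) standard errors are available behind a
flag, computed by hand from the per-subject score contributions with the
variance components held at their ML estimates, since the mixed-model
machinery used for fitting does not expose them; model-based SEs are the
default. Confidence intervals and p-values are normal-based (half-width
1.96·SE), two-sided α = 0.05, no multiplicity adjustment.

Cohen's *d* is reported two ways because they differ materially here:
change-score standardisation divides the change-difference by the pooled
baseline SD (3.950 for ISI at the published baseline ns), endpoint
standardisation divides by the model-implied follow-up SD
√(τ² + σ²). The standardiser is always reported next to *d* rather than
forcing one convention.

## Response and remission

Response is a drop of at least 8 ISI points from baseline; remission is a
wave ISI below 8. Contrasts are observed-case (no imputation), tested with
Pearson's chi-square without continuity correction, and interval-estimated
with the Newcombe hybrid score method assembled from per-arm Wilson limits:
lower = (p₁−p₂) − √((p₁−l₁)² + (u₂−p₂)²), upper analogous.

## Pattern-mixture models

"Complete" means the outcome is observed at both the 6-month and 2-year
follow-ups. PMM1 fits the change model within the complete and incomplete
strata and averages the between-arm differences with stratum-proportion
weights. PMM2 crosses completeness with arm; since a one-arm stratum
cannot identify a between-arm contrast, each arm-pattern cell contributes
its own change-from-baseline trajectory (wave-only random-intercept model),
arm-level changes are averaged across that arm's pattern strata, and the
contrast is the difference of the averaged changes — which reduces to PMM1
when patterns and estimates coincide across arms. Stratum SEs combine
under an independence assumption, √(Σ(wᵢ·SEᵢ)²). An inestimable stratum
falls back to the overall-model estimate and is flagged in the report; the
exact identification device the original SEM-based analysis used for
incomplete strata is not recoverable from the published description, so
the stratified available-data fit is documented output metadata rather
than a claim of mechanical equivalence.

## Multiple imputation

Chained equations with predictive mean matching, run separately per arm.
Variables (clinical scores, SF-6D, resource indicators across all waves)
are visited in order of increasing missingness; each incomplete variable is
regressed on all others plus age and sex; coefficients are drawn from their
approximate normal posterior (type-1 matching); each missing case receives
the *observed* value of one of the k = 5 nearest predicted-mean donors,
drawn uniformly (ties and neighbourhoods resolved by a seeded generator).
Ten chained iterations, m = 50 imputations by default. Structurally missing
cells (WPAI hours of non-employed participants) are never imputed. Pooling
uses Rubin's rules, T = W̄ + (1 + 1/m)B, with Barnard–Rubin small-sample
degrees of freedom when a complete-data df is supplied.

## Tipping point

The delta adjustment is operationalised as impute-shift-pool: impute all
missing outcome values under MAR, add δ to the *imputed* 2-year values of
the shifted arm only (the comparator stays MAR), re-estimate the 2-year
contrast per imputation, pool, and scan δ. Because δ moves a fixed set of
already-imputed cells in completed (hence balanced) data, the per-imputation
estimate is exactly linear in δ with slope equal to the imputed fraction of
the shifted arm, and the within-imputation variance is unaffected by a mean
shift of a fixed cell set; the whole grid (default 0 to 3 by 0.01 ISI
points) is therefore evaluated in closed form from one model fit per
imputation. δ* is the smallest grid value whose pooled 95% interval covers
zero; if the grid is exhausted the result says so and reports the terminal
estimate. At the full trial size with default calibration the analysis
lands near δ* ≈ 1.2–1.4 with the contrast attenuated to around −0.9, the
qualitative shape the published sensitivity analysis reports.

## Mediation

Linear mediator (ISI at 9 weeks) and outcome (HADS/CFQ at 2 years) models,
adjusted for age and sex, observed-case. Without interaction, ACME = a·b,
ADE = c′ and TE = ACME + ADE exactly; the package asserts agreement with
the product-of-coefficients oracle at 1e-8 on every test fit. An optional
treatment×mediator interaction variant averages the arm-specific effects
over the two arms. Intervals are percentile bootstrap over participants
(B = 1000, seeded); BCa was not used because the framework being mirrored
defaults to percentile intervals. "Full mediation" is only a descriptive
flag (ADE interval covers zero while ACME's excludes it), not a test.

## Costs and QALYs

QALYs integrate the piecewise-linear utility curve through each
participant's observed SF-6D points (trapezoid rule; fewer than two points
leaves the QALY undefined for that participant, to be handled by MI);
there is no discounting, as costs and outcomes cannot be separated by year
at these assessment times. Costs per participant, converted at 9.85
NOK/EUR:

* **Programme**: €70.16 (dCBT-I) / €23.80 (PE) per participant.
* **Medical**: each 3-month-recall visit indicator is treated as a
  quarterly visit probability, linearly interpolated between waves,
  integrated over the horizon and multiplied by a configurable expected
  visit count per quarter (default 1.0) and a unit cost. Sleep-medication
  indicator days are valued at a per-day price.
* **Productivity**: WPAI absenteeism and presenteeism hours/week are
  carried piecewise-constant between waves, multiplied by weeks in each
  interval and the national mean hourly wage (human-capital approach, no
  friction period), for employed participants only. Presenteeism responses
  enter directly as hours/week.
* **Out-of-pocket**: copayments per estimated visit volume, behind config.

The shipped unit costs (GP 420 NOK, psychiatrist/specialist 1050 NOK,
sleep medication 2 NOK/day, wage 290 NOK/h, copays 155/351 NOK) are
configurable placeholders on the order of Norwegian tariffs, not calibrated
quantities; every acceptance-relevant number flows through the printed
programme costs, group means, or the generator, never through these
defaults. Perspectives are component masks: societal = programme + medical
+ productivity + out-of-pocket; healthcare = programme + medical; employer
= programme + productivity; patient = programme + out-of-pocket — so the
societal total partitions componentwise by construction.

Incremental quantities are dCBT-I minus PE group means with model-based
(OLS) intervals; the ICER is ΔC/ΔE with an explicit quadrant label
(dominant / dominated / trade-off), since a lone negative ratio is
ambiguous. Uncertainty comes from bootstrap resampling of participants
with replacement, stratified by arm, preserving each participant's
cost-QALY pairing (B = 1000, seeded); CEAC(λ) is the fraction of replicates
with non-negative net monetary benefit, evaluated on a WTP grid with the
reference threshold at €30,000/QALY. One-way deterministic analyses vary
the dCBT-I programme price (closed-form break-even
p* = c_PE + λ·ΔE − ΔC_nonprogramme, defined only when ΔE > 0) or apply
multiplicative uplifts to dCBT-I medical/productivity costs. MNAR scenario
grids cut dCBT-I QALYs by 5–20% and raise dCBT-I costs by 5–20% and
recompute everything per cell.

## Synthetic-trial generator

The generator is the package's test bed and defines the study conditions:
two arms of 867/853, outcome y = arm-wave mean + person intercept +
residual, scores rounded and clipped to instrument ranges, residual SDs
derived per arm-wave so the *marginal* SD matches the published arm-level
SD given the configured intercept SD. Arm-wave means for ISI, BIS, HADS,
CFQ, activity impairment, resource-use probabilities, WPAI distributions
(zero-inflated lognormal, employment fixed at baseline with probability
0.67) and retention targets are calibrated to the published arm-level
tables. Values the publication does not print were fixed once:

* **9-week means** (the short-term results are published separately): ISI
  post means chosen so the 9-week change difference reproduces the
  published short-term effect size d ≈ −1.21 on the pooled baseline SD;
  other instruments interpolated between baseline and 6 months.
* **PE 2-year ISI mean** set to 12.87 so the *generating* 2-year change
  difference equals the published model estimate −1.77. Completer means
  are selection-shifted under dropout, so the printed completer mean
  (13.4) cannot double as the generating truth.
* **Utility link**: SF-6D = 0.6735 − 0.00446·ISI + noise, clipped to
  [0.29, 1], calibrated to reproduce the published utility means at the
  published ISI means (≈0.587 at ISI 19.4, ≈0.62 at ISI 12). For studies
  that need exact control of the utility AUC the generator accepts an
  explicit arm×wave utility-mean table instead; the planted-QALY
  configuration sets the unprinted 9-week utility offset so the
  trapezoid-AUC difference equals the published incremental QALY 0.025
  exactly under the wave clock above.
* **Within-person correlation** is not published; intercept SDs (e.g. 3.0
  ISI points) are calibration choices giving moderate positive
  wave-to-wave correlation.

Dropout is monotone: once a wave is missed all later waves are missing.
Per arm and wave, the dropout hazard is logistic in standardised baseline
ISI and age (MAR), with the intercept solved on the realised sample so the
marginal retention matches the published targets (67/65% at 9 weeks taken
between baseline and the published 6-month retention; 49/45% at 6 months;
36/32% at 2 years). Under MNAR the linear predictor adds γ times the
standardised current, about-to-be-missing ISI; γ = 0 reduces exactly to
MAR. The pre-dropout table is retained as a shadow for oracle tests.

What the generator does **not** emulate: item-level instruments,
engagement/adherence structure (no CACE), registry-linked resource use,
non-monotone intermittent missingness, and any genuine joint law between
clinical outcomes beyond the shared-intercept-within-outcome structure
(outcomes are generated independently given arm and wave, so cross-outcome
mediation effects are zero unless planted with the dedicated mediation
generator). Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the stated generating law, not robustness
to the full complexity of real trial data.

## Problem sizes and determinism

The replicate studies use 200 replicates at the full sample size for the
change-model and QALY recovery (per-replicate SE ≈ 0.43 ISI points and
0.006 QALYs, so the Monte-Carlo SEs of the reported means are ≈0.03 and
≈0.0004). The MI coverage study runs at 150 participants per arm with
m = 10 and 200 replicates, using the saturated complete-data estimator
per imputation — a deliberate scale-down that preserves the property under
test (nominal coverage of Rubin-pooled intervals under MAR). A small
upward truncation bias of order 0.05 ISI points in recovered 2-year
contrasts is expected from rounding/clipping scores to instrument ranges
at the configured noise levels; it is an order of magnitude inside the
replicate spread. All randomness flows from seeded generators
(`numpy.random.default_rng`); the pipeline fans one top seed into
per-stage sub-seeds via `SeedSequence.spawn`, and every stochastic output
is bit-reproducible under a fixed seed.

## Known limitations

* Printed effect sizes imply a standardiser slightly different from the
  pooled printed baseline SDs (≈4.1 vs 3.95 for ISI); the package reports
  the standardiser rather than forcing agreement.
* The published total-cost and ICER figures derive from unrounded
  trial-level inputs; from the rounded printed means one obtains −278/0.025
  = −11,120 €/QALY rather than the printed −10,973, so printed-value checks
  are plausibility checks, not identities.
* Appendix-only quantities (exact unit costs, visit-volume estimation
  rules, the 6-month interim weighting) are represented by configurable
  placeholder rules, isolated behind `EconConfig` so appendix-faithful
  variants can be swapped in.
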