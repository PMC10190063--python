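# Methods

## Model structure and assumptions

The model is a single-shot decision tree, not a Markov model: each
strategy's whole course is collapsed into expected cost and expected QALYs,
with no per-cycle chemotherapy calendar and no half-cycle correction. Costs
and utilities are undiscounted, which is defensible for time horizons of at
most a few years. Effectiveness is catheter survival time multiplied by a
health-utility weight; complications act in two ways — they add a
mix-weighted management cost and they switch the utility weight from the
complication-free to the with-complication value, both applied once per
patient course (not once per CVC insertion episode). With that convention
the tree's expected values factorize into the closed forms in the README,
and they equal brute-force enumeration over the 27 terminal branches to
1e-9 (asserted in the tests).

The CVC arm is a composite of repeated short catheterizations: `mean
insertions` episodes, each with its own insertion/maintenance/removal cost
and a median per-episode dwell, separated by intermissions lived at a lower
utility. Its outcome is therefore invariant to the dwell-time scenario —
the cycle spans whatever course the patient needs — while PICC and IVAP
outcomes cap the catheter time at `min(dwell, median survival)`.

**Time conventions.** A month is 30 days and a year 365 days, except that
a whole multiple of 12 months maps to whole years ("6m" = 180/365 y, "12m"
= 1.0 y). Maintenance visits accrue fractionally at one visit per
maintenance interval (0.0192 y PICC, 0.0822 y IVAP); with 0.0822 y ≈ 30.0
days this single rule reproduces both the 6-month (≈6 visits) and 12-month
(≈12.17 visits) published cost cells without special-casing visit counts.

## Parameters and their dispersions

Every base-case input (costs, probabilities, utilities, survival medians,
CVC cycle statistics) lives behind a stable string key; the 37 keys with an
assigned distribution are exactly the parameters eligible for sensitivity
analysis. Two distinct dispersions are attached to a cost parameter:

* **patient-level SD** — the printed SD, falling back to interval-width/3.92
  — drives the synthetic cohort's itemized cost draws;
* **standard error of the mean** — interval-width/3.92 when a 95% CI of the
  mean is printed, else the printed SD, else 10% of the mean — drives
  parameter uncertainty in the probabilistic sensitivity analysis. PSA
  parameter uncertainty is uncertainty about the *mean*, not patient-level
  noise; conflating the two makes arm costs swap order randomly and
  destroys the known base-case orderings.

The two per-visit maintenance intervals (PICC 0.433–42.92, IVAP
0.64–63.64) span nearly ±100% of their means while every other cost row's
CI halfwidth is about 2% of its patient SD; they are therefore read as
patient-level 95% ranges, and their SE is range-SD/√n with n the arm size.
The deterministic (tornado) analysis, by contrast, deliberately uses the
printed intervals as excursion ranges (or ±10% when no interval exists),
clipped to each parameter's support.

Sampling families follow standard health-economics practice: gamma for
costs (shape = (m/sd)², rate = m/sd²), beta for utilities (method of
moments) and for complication probabilities (Beta(events, n−events) from
the published event counts), normal for the CVC cycle statistics. The
normals are truncated at their plausibility bounds (durations ≥ 0,
insertions ≥ 1) with the location re-solved so the truncated mean still
equals the base-case value — PSA outcome means must sit on the base case
for the analysis to be interpretable. Median survival is sampled through
the fitted family: a mean-matched lognormal on the median itself for CVC,
and for PICC/IVAP a normal perturbation (10% coefficient of variation) of
the Gompertz rate with the median recomputed; the 10% CV is a convention,
chosen once, because no hyperparameters are published. Complication-type
mixes are held fixed in the PSA; only the overall probabilities are
sampled.

## Survival fitting

Catheter removal is treated as the event and everything else as right
censoring (cause-agnostic survival, not a competing-risks estimand — only
medians feed the decision model; which record labels count as events is an
``event_labels`` flag on the estimator, so alternative conventions plug
in). Four families are fitted by censored maximum
likelihood through one generic routine (events contribute log f, censored
observations log S) so that AIC = 2k − 2ℓ is comparable across families;
the minimum-AIC family wins, ties broken toward fewer parameters, and fits
over different data are refused via a data fingerprint. The Gompertz uses
hazard h(t) = b·e^{at} with S(t) = exp(−(b/a)(e^{at}−1)) and median
ln(1 + a ln2 / b)/a. Optimization is Nelder–Mead from a small deterministic
grid of starts (the Gompertz likelihood can be flat in the shape/rate
trade-off), with the exponential seeded at its closed-form MLE
events/total-time. A Kaplan–Meier estimate (lifelines) provides the
nonparametric cross-check, and lifelines' own parametric fitters serve as
an independent oracle in the tests for the three families they cover.

## Synthetic cohort

The generator emulates the structure the pipeline assumes, not any real
hospital extract. Free choices, fixed once:

* covariate marginals typical of a Chinese breast-cancer chemotherapy
  cohort: age N(50, 10) clipped to [18, 85], ~99.5% female, Han ethnicity
  93%, three education levels, height N(158.5, 5.8) cm, weight
  N(59.8, 8.9) kg, comorbidity prevalences 4–18%;
* expected pre-matching arm sizes 4823/1608/4287 (total 10,718);
* device assignment by multinomial logit: a shared standardized confounder
  signal (default: age, weight, hypertension, thrombosis history) pushes
  patients toward IVAP and away from PICC, producing the baseline imbalance
  matching must remove; with all coefficients zero the groups are
  exchangeable;
* catheter survival: lognormal with σ = 0.5 for CVC; Gompertz shapes
  2.0/y (PICC) and 0.7/y (IVAP) — hazard doubling every ~4 months and ~1
  year respectively — with rates solved from the target medians;
* CVC episode counts 1 + Poisson(mean insertions − 1), preserving the
  published mean;
* censoring by an *independent* exponential time whose rate is calibrated
  so the expected censored share equals the configured fraction (default
  10%; the source analysis does not report censoring prevalence). Drawing
  the censor time from the patient's own event time — the obvious shortcut
  — is informative censoring and biases fitted medians upward by 2–4%,
  which is why it is not used.

What passing the recovery tests shows: the estimator returns the
generator's truth (probabilities ±0.005, component cost means ±2%, medians
±3% at n = 10⁵). What it does not show: robustness to features real
billing data would add — skewed cost outliers beyond gamma tails,
informative censoring, miscoded complication types, calendar effects.

## Matching

Three groups are matched through two pairwise logistic propensity models
(PICC vs CVC, PICC vs IVAP; statsmodels GLM on the 11 covariates). Each
PICC patient, in seeded random order, greedily takes its 2 nearest
available CVC and 2 nearest available IVAP neighbours on the probability
scale within a caliper of 0.1 (a logit-scale caliper is exposed as a
flag); matching is without replacement and a stratum failing either
comparison is dropped whole, so the matched cohort has the 1:2:2 shape by
construction. Balance is summarized by the maximum absolute pairwise
standardized mean difference plus one-way ANOVA (continuous) or Pearson χ²
(categorical) across the three groups; constant covariates are skipped
with a note.

## Numerical choices and degenerate inputs

* Parametric fits require ≥ 10 uncensored events and strictly positive
  times; all-censored data are refused.
* Sampling distributions with SD 0 collapse to point masses; an infeasible
  beta SD (sd² ≥ m(1−m)) is an error naming the parameter.
* The truncated-normal location shift and the censoring-rate calibration
  are solved by Brent's method to 1e-12, using the erfcx-based Mills ratio
  for numerical stability far into the tails.
* ICERs are defined only when cost and QALY increments share a sign;
  otherwise a dominance flag is reported. The recommendation maximizes net
  monetary benefit (ties broken toward lower cost), which agrees with the
  dominance-pruned ICER-ladder decision on every frontier (property-tested
  against a brute-force ladder oracle).
* The CVC tie `intermissions = insertions − 1` is enforced for base-case
  and user-loaded parameter sets but deliberately *not* re-imposed when
  sensitivity analyses perturb either quantity alone, since each carries
  its own published distribution.

## Problem sizes

The test suite exercises the recovery loop at 10⁵ patients, AIC family
selection at 20 replicates of n = 5000 (where the selector identifies the
generating family in 20/20 replicates per arm), and the probabilistic
analysis at 10⁴ draws with a 201-point willingness-to-pay grid — sizes at
which every sampling-error tolerance above is comfortably justified by the
corresponding standard errors.

## Known limitations

* The published probabilistic-analysis percentages (95%/4.2%/0.8%) and the
  CEAC crossover near \$3,479/QALY depend on undisclosed distribution
  hyperparameters; this implementation checks the qualitative structure
  (CVC optimal at WTP 0, a single CVC→IVAP crossing, IVAP dominant at the
  national threshold) rather than those exact figures. Under the
  moment-matched distributions used here the crossing sits lower, between
  \$500 and \$1,000/QALY.
* The 12-type × 3-arm complication-type contrast is computable with the
  generic χ² operation, but its published value depends on an unknown
  zero-cell convention and is not asserted.
* Utilities are consumed as point inputs from the published survey; the
  survey instrument and tariff scoring are out of scope.
* No currency-inflation adjustment; the RMB/USD rate is metadata only.
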