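# Methods

`nutriprofile` implements a personalized-nutrition pipeline for
cardiovascular disease (CVD) prevention: food-preference profiling from a
140-item liking questionnaire, CVD risk prediction, survival-based
derivation of per-profile optimal nutrient intake ranges, and a two-level
rule-based recommendation engine. This note records the models, the
defaults and the design choices made where the design was genuinely open.

## Synthetic cohort

All statistical machinery is exercised on synthetic cohorts with planted
structure, generated by `nutriprofile.cohort`. The generator emulates the
schema of a large UK population cohort of middle-aged adults; it does not
attempt to mimic any real cohort's field coding or withdrawal logic.

* **Liking scores.** 140 items partitioned into four food groups
  (fruit/veg 40, meat/fish 35, sweetened items 30, other 35). Each of the
  three profiles has a mean liking per group (defaults: health-conscious
  7.5/4.5/3.0/5.0, omnivore 6.0/7.0/5.5/6.0, sweet-tooth
  4.5/4.5/7.5/4.5 on the 9-point scale, SD 1.5). Draws are rounded to
  integers and clipped to [1, 9]; the published split thresholds (<3, ≥8,
  ≥7) require at least that range. Distributional forms per profile are
  not documented anywhere authoritative; these are free knobs chosen to
  give roughly 3-SD group separation, under which the mixture model and
  the simplified tree are both expected to work well — passing tests
  therefore show correctness of the machinery, not that real liking data
  are this well separated.
* **Profile mix.** Mixing weights default to 0.35/0.40/0.25; each
  component must hold ≥ 10% of the cohort, mirroring the
  minimum-profile-size rule used when the profiles were defined.
* **Outcome.** CVD is Bernoulli from a logistic model. The configured
  per-profile odds ratios (defaults 0.74, 1.16, 1.17) are **group-vs-rest**
  contrasts, so the generator solves (deterministic least squares on the
  log-odds scale) for the three per-profile baseline logits that
  reproduce those contrasts exactly under the configured mixing weights
  while keeping the marginal prevalence at `baseline_cvd_prob`
  (default 0.15). Naive log-OR offsets against a shared intercept would
  *not* reproduce group-vs-rest odds ratios. Small mean-centred intake
  terms (e.g. 1.6·10⁻⁵ per kJ of energy) are added so nutrient
  coefficients can be recovered.
* **Onset age.** Age in years is the time axis (no calendar time). Onset
  is Weibull (shape 3, baseline scale 28 years past age 40) with the
  scale multiplied by exp(−η), where η is linear in the standardised log
  intakes (`intake_hazard_coefs`), so higher-risk intakes have earlier
  onset. Setting `intake_risk_shape="ushape"` makes η quadratic
  (η ∝ z²−1), planting a safest-in-the-middle intake pattern used to
  validate the limit-derivation logic. Non-cases are censored at
  `censor_age` (default 68).
* **Missingness.** 5% of liking, intake and clinical measurement cells
  are set missing completely at random to exercise imputation.

## Latent profile model

`fit_latent_profiles` fits Gaussian mixtures by EM (scikit-learn
`GaussianMixture`) for each candidate component count (default 2–9),
scores each with BIC on the 2·logL − penalty convention (larger is
better), discards candidates whose smallest max-posterior component holds
under 10% of participants, and selects the best admissible candidate.
The covariance family is per-component full covariance by default; a
`shared_shape=True` flag switches to tied covariance as an approximation
of an equal-volume/equal-shape ellipsoidal family, whose exact
parameterization is not reproduced here. Missing liking values are
handled by alternating rounds of posterior-weighted component-mean
imputation and EM refits (3 outer rounds). Components are mapped to the
named profiles by liking signature: highest fruit/veg mean →
health-conscious; highest sweetened-item mean among the rest →
sweet-tooth; remainder → omnivore. Posterior ties resolve to the lowest
component index.

## Simplified questionnaire classifier

The packaged canonical tree asks at most three of its 14 items: tea with
sugar < 3 (strict) sends a user left, where vegetables ≥ 8 (inclusive) →
health-conscious; tea with sugar ≥ 3 sends right, where roast chicken ≥ 7
→ omnivore and < 7 → sweet-tooth. Two leaves are not pinned down by the
narrated structure: the (tea < 3, vegetables < 8) leaf is assigned
omnivore (the largest group, a conservative fallback), and the packaged
leaf class distributions are illustrative placeholders, not measured
values. `train_simplified_tree` re-derives such a tree from data: a CART
probe on all items ranks them by impurity importance, and the final tree
is refit on the top `max_items` (default 14) items.
`feature_importance` cross-checks item relevance with three methods:
random-forest impurity importance, L1-penalised multinomial logistic
coefficients on standardised features, and a Monte-Carlo Shapley
attribution of the forest's predicted class probabilities (permutation
sampling against a column-mean background), combined by mean rank.

## Risk prediction harness

Three predictor sets are supported: *framingham* (age, sex, SBP, DBP,
total cholesterol, HDL, BMI, waist circumference + smoking and
hypertension flags), *diet* (six average daily intakes + age, sex, BMI,
WC + the same flags) and *fpp* (non-blood measures + the food-preference
profile). Missing cells are completed by k-nearest-neighbour multiple
imputation (k=5, m=5 by default): nan-aware Euclidean distances on
standardised columns; each of the m imputations fills a cell with the
mean of a seeded bootstrap resample of the k nearest donor values,
giving between-imputation variability while leaving observed cells
untouched (k=1 copies the unique nearest donor).

Per imputed table the protocol is: stratified 70/30 train/test split
(split seed separate from fold seed), 10-fold stratified CV on the
training portion producing out-of-fold probabilities, classification
threshold chosen by maximising training accuracy over a 0.01 grid, refit
on the full training portion, metrics on the held-out 30%. Reported
metrics: accuracy (test, at the chosen threshold), AUC and AUPRC (pooled
out-of-fold training predictions) and the C statistic, implemented as the
concordance of predicted probability with the binary outcome on the test
split — a documented interpretation, since a time-to-event concordance
would need a survival risk engine that is out of scope. Metrics are
pooled across imputations by simple averaging; nutrient coefficients are
pooled by the Rubin's-rules mean. Model families are logistic
regression, LDA, random forest and RBF-SVM (probabilities via the
Platt-style sigmoid fitted on internal cross-validation of the training
data), all behind a standardising pipeline.

The 0.41 probability threshold that separates low from high risk in the
recommender is of the same kind as the harness's accuracy-optimal
threshold; it ships as a fixed packaged default, and callers may
substitute a freshly optimised one.

## Nutrient limits

`km_estimate` is a direct product-limit implementation (ties between
events and censorings at one age keep censored subjects at risk at that
age); it is cross-checked against an independent survival library in the
tests. `prepare_survival_cohort` removes participants diagnosed before
their first dietary recall and right-censors all follow-up at 68 years.
`derive_limits` splits a profile's intake into equal-frequency bins —
the operative bin count is 4 (configurable); ties that prevent distinct
boundaries reduce the count with a warning — estimates a KM curve per
bin, and ranks bins by restricted-mean survival to the censoring age
(ties: later median onset, then lower bin index). The best bin's intake
boundaries become (min_val, max_val). An optional bootstrap stability
score (fraction of resamples agreeing on the best bin) flags nutrients
with no real effect, whose selected bin is unstable. Trans-fatty acids
have no known safe lower limit; their minimum is forced to 0.

The published constants (required change and optimal range per profile ×
six nutrients) ship as package data (`data/table3.yaml`), schema-checked
on load. Whether those ranges came from a single best bin or a composite
of extreme bins is not documented; this package reports the single best
bin and treats the packaged numbers as authoritative constants.

## Required change and the adjustment rule

The required change converts a target risk decrease into an intake
change through the per-profile logistic coefficient: ΔN = ΔR/β. ΔR is
interpreted on the log-odds scale (default 0.01), the only scale on
which the relation is linear in β; a helper converts a
probability-scale target to log-odds locally at P = 0.41
(ΔR_logit = Δp / (p(1−p))).

The adjustment rule fires only when the predicted probability strictly
exceeds the threshold (P > 0.41) **and** the reported intake lies outside
the optimal range. The published ΔN values are negative (all profiles
must reduce intake), while the rule adds ΔN below the minimum; the
engine therefore applies the **magnitude** |ΔN| toward the range — the
only reading under which both branches move intake into [min, max]. A
clamp (not part of the published rule) stops a large step from crossing
the entire range: if it would, the intake settles at the violated bound.
Under this rule the distance from the intake to the optimal interval
strictly decreases whenever a rule fires; note a step may legitimately
land *inside* the range past the violated bound, so distance to the
nearest bound alone is not monotone.

Message routing: P ≤ threshold → single M4; otherwise per nutrient M5
(below range, increase), M6 (within, maintain), M7 (above, decrease).
Level-1 portion feedback compares weekly portions of five animal-protein
food groups to editable reference portions (placeholders in the spirit of
UK portion guidance: oily fish 1/week, non-oily fish 1/week, poultry
2/week, red meat 2/week, processed meat 1/week) and routes M1 (below,
with profile-specific and plant-based options), M2 (exactly at the
reference — a maintenance message, inferred rather than documented) or M3
(above, reduce red/processed meat). Message texts are illustrative
strings in a localization table keyed by (message id, profile variant);
the structure, not the wording, is the contract.

## Problem sizes and numerical choices

The test suite uses cohorts of 800–5,000 participants for mixture and
tree checks, 20,000 for odds-ratio recovery, and 10,000 for the planted
U-shaped limit-derivation check; these sizes give comfortable power for
the planted effects while keeping the default suite under a minute of
mixture fitting. EM uses `reg_covar = 1e-4` for numerical stability on
integer-valued scores; posterior rows are normalised to 1 within 1e-9.
All stochastic fits take explicit seeds (package default 83988).

## Known limitations

* The synthetic generator's group separation, prevalence and effect
  sizes are defaults, not estimates; real liking data are noisier and
  the published performance figures (accuracies ≈ 0.72, per-class
  F1 0.66–0.71) are not reproducible without the restricted source data.
* The mixture covariance family approximates, but does not replicate,
  the equal-volume/equal-shape ellipsoidal parameterization.
* The C statistic is binary concordance, not a survival concordance.
* No Cox modelling, competing risks or time-varying diet; the level-1
  engine has no vegetarian flag (zero animal-protein portions simply
  route to M1 with plant-based suggestions).
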