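# Methods

This note documents the models and procedures `kinrisk` implements, the
conventions it fixes where the underlying constructs leave choices open, and
what the synthetic registries do and do not establish.

## Data model

A registry is three tables — persons (`person_id, dob, gender,
ethnicity_group`), directed relationships (`subject_id, object_id,
type_code, recorded_date`), events (`person_id, event_type, date`) — plus a
taxonomy mapping each relationship type code to its semantics: whole-life
(parent/child, sibling, half-sibling), abusive (with the instigating role,
subject or object, identified), or other. All timestamps are calendar
dates; relationship timestamps are **recording** dates, not start dates.
Operational taxonomies run to over a hundred types and are not public, so
the shipped default is a ~12-type synthetic taxonomy covering the three
semantic categories; it is a configuration input, not a constant.
Validation enforces referential integrity, collection-window containment
(default 1996-01-01..2016-12-31; descriptions of when such registries began
collecting are not always consistent, so the window is a parameter rather
than a constant), presence of dobs wherever whole-life backdating needs them,
and drops exact duplicate relationship rows with a logged count.
`load ∘ write` is the identity on validated databases and validation is
insensitive to input row order.

## Cohort and response

One analysis row per notification event. The lifetime index `j` counts
*all* of a child's notifications in date order (same-day ties broken by
event-table row order, logged), while eligibility — dob known, date within
the event window (default 2006-01-01..2013-12-31), under 16 completed years,
follow-up window ending inside the collection window — is flagged with the
first failing reason. Estimated concern uses the follow-up window
`(T, T + 2 calendar years]`: strictly after `T`, closed on the right, so
the index notification's own same-day records belong to neither past nor
future; the same convention mirrored backwards (`[T − 2y, T)`) defines the
"recent" feature windows. "Calendar years" means anniversary arithmetic
(Feb 29 anniversaries land on Feb 28). Rule (iii) — a referral decision at
a *subsequent* notification — is approximated by any `referral_decision`
event in the window, because the event schema ties referrals to the child,
not to a specific notification; with referral decisions recorded within
days of their notification the approximation only miscounts referrals
attached to the index notification itself but dated inside the window.
`followup_years` is configurable for sensitivity analyses.

## Networks and features

Recorded membership at `T`: any relationship row touching the child (either
direction, any type) with `recorded_date` strictly before `T`. Whole-life
membership: whole-life-type rows only, effective from the dob of the
younger member, included iff that date is `≤ T` — a child born on `T`
exists at `T`. Members lacking a dob cannot be backdated and are excluded
with a log message. Only membership is backdated: member attributes (their
notifications, target events, recorded abusive-instigation rows) are always
evaluated against `T` with no backdating, under both semantics. In
particular, "known abuser" means an abusive row *recorded* before `T` in
which the member holds the instigating role — with anyone, not only the
child; instigation recorded after `T` is invisible even when the underlying
abuse predates it, an interpretation chosen to avoid lookahead.

`nWithNotes*`/`nWithTarget*` count only members who are themselves
children; the cutoff is under 16 completed years at `T`, matching the
sample's own age filter, since no other threshold is defined anywhere in
the data. `nNeighsR` counts adults and children. The whole-life network
size is never emitted (it measures registry coverage, not family
structure), prior referral counts are never features (to avoid feedback
from past decisions), and gender/ethnicity are never features. The
abbreviation "nWithContactW" occasionally appears in this literature as an
alternative label for `nWithNotesW`; it is treated as a naming variant, not
a thirteenth feature. Extended (2–3 hop) networks are out of scope.

Two implementations exist deliberately: per-case functions
(`recorded_network`, `whole_life_network`, `case_features`) that scan one
child at a time, and a vectorised `feature_matrix`; tests assert row-level
agreement between them and against brute-force oracles.

## Models

Logistic regression is fitted by Newton/IRLS, tolerance 1e-8 on the largest
coefficient change, at most 100 iterations, no regularisation. Steps larger
than 10 in sup-norm are scaled down for stability; a singular information
matrix (collinear or constant columns — common in small subsamples where
`nAbusersR` and `nAbusersW` coincide) falls back to the minimum-norm
pseudoinverse step, which leaves predictions and the likelihood
well-defined; genuinely separating data are detected by diverging
coefficients and raised as an error advising penalisation rather than
silently applying any.

Cross-validation uses K = 10 random folds at notification level — the same
child may appear in training and test folds, which is stated behaviour
(each notification is a separate decision point); a child-grouped mode
exists as an option. The ROC score is computed once on the pooled
out-of-fold predictions (per-fold averaging is a possible alternative; the
pooled choice is stated and fixed). Reported coefficients, standard errors
and AIC come from the full-data fit; AIC is the standard 2k − 2 ln L with k
counting the intercept. The best-subset search enumerates every
{age + 3 others} model from the requested pool (events-only,
events+recorded, or all), ranks by ROC score with AIC reported alongside,
and appends the full-pool model. First-notification searches drop the
event-based features (identically zero there). Quadratic interaction terms
are excluded; nothing in the implementation depends on them.

## Stumps

A depth-1 tree on one predictor is the Gini-optimal threshold over
midpoints of consecutive sorted unique values; "high-risk" means strictly
above the threshold, so no case can sit on a candidate. Ties in impurity
decrease go to the smaller threshold. K training-fold refits are compared
with the full-data threshold; disagreement (expected only in small samples)
is a warning, not an error. Per age bracket — default single completed
years 0..15, edges configurable since no canonical bracketing exists — the
analysis reports the incidence of high estimated concern in the high-risk
group (PPV) and low-risk group (false omission rate); these satisfy the
exact identity Σ(PPV·n_high + FOR·n_low) = total positives.

## Fairness audit

Calibration uses equal-frequency score bins (robust to skewed score
distributions) with exact Clopper–Pearson intervals on observed incidence;
calibration-in-the-large is observed incidence minus mean prediction. Group
error rates (FPR, FNR, per-group ROC) are evaluated at a shared operating
threshold, defaulting to the score quantile matching the cohort's positive
rate — no operational threshold is defined anywhere, and this choice flags
exactly as many cases as there are positives. Group-vs-rest differences
carry normal-approximation intervals; because notifications of siblings and
of the same child are correlated through shared family risk, the audit
accepts a `clusters` argument and then uses cluster-robust (linearised)
proportion variances — the pipeline clusters by child, and tests cluster by
ground-truth family. The audit only ever joins gender/ethnicity onto scored
cases after fitting; the feature matrix has no such columns to leak.

## Synthetic registries

The generator emulates the statistical structure the analysis depends on,
not the demography of any jurisdiction.

* **Pedigrees**: two generations — mother, father (probability 0.75),
  optional step-parent (0.2), 1 + Poisson(1.8) children (mean 2.8, capped
  at 8), each child a half-sibling with probability 0.25. Ethnicity labels
  (three synthetic groups) and genders are assigned independently of
  everything else, so groups are exchangeable by default; a per-ethnicity
  recording override exists to plant group-specific censorship.
* **Latent risk**: one Normal(0, 1) scalar per family enters all hazards
  log-linearly and all response probabilities on the log-odds scale
  (default effects 0.8). This is a stand-in: the analysis asserts no
  generative model, and a single family-level factor is the simplest
  process that makes family history genuinely predictive of a child's
  future outcomes.
* **Events**: notifications are exact daily Bernoulli draws (binomial count
  per (child, year-of-age) segment, then distinct days), baseline 0.15 per
  child-year, declining 4%/year of age, up to age 17 so that the under-16
  eligibility filter has work to do. Each notification then triggers, with
  risk-dependent probabilities (baselines: referral 0.30, substantiated
  finding 0.12, conference 0.06, agreement 0.06, intervention 0.08), a
  follow-up event at a short lag. Coupling responses to notifications makes
  every family's first event a notification, which keeps the censorship
  property below sharp.
* **Recording censorship**: each family relationship row is recorded early
  (probability `p_record_before_target`) shortly after its effective date,
  or else only after the family's *first target event*, with an
  exponential delay (mean 365 days — family mapping accumulates over about
  a year of involvement, and a materially shorter delay would let recorded
  networks catch up with whole-life networks almost immediately); families
  with no target event are recorded at the end of the window. Abusive rows
  (adult instigator, adult victim) have independent uniform recording
  dates: they arise from the instigator's own past cases.
* **Presets**: `null_risk` (all effects zero — every downstream signal
  should vanish), `planted_risk` (positive effects, 90% early recording),
  `censored_recording` (positive effects, 5% early recording). Defaults
  target statistical power at roughly 20,000 children (7,000 families).
* Ground-truth side tables (latent risks, true pedigree) are written for
  test oracles only; the pipeline never reads them. Optional dob jitter of
  up to 7 days emulates anonymisation noise and defaults to 0.

What passing tests on these registries establish: the pipeline's temporal
logic is exact (oracle equivalence), estimators are correct (parameter
recovery, ROC/AIC identities), and the whole-life-vs-recorded ordering
follows from recording censorship plus family-clustered risk. What they do
not establish: effect sizes, incidence rates or ROC magnitudes for any real
registry — real data have richer relationship taxonomies, time-varying and
child-level risk, reporting biases, and recording processes the
single-trigger model only sketches.

## Numerical and degenerate-input conventions

Empty databases, empty cohorts and empty brackets flow through as empty
outputs, not errors; zero families is a valid configuration. Constant
predictors are an error for stumps and are skipped by nothing — subset
search candidates that cannot be fitted surface their error naming the
spec. ROC requires both classes. Calibration bins merge (with a warning)
when tied scores make quantile edges collide. All randomness flows from
explicit integer seeds: the generator from its config seed, fold assignment
from the fit seed; two runs of the pipeline with equal config and seed
produce byte-identical artefacts and manifests (wall-clock timing is logged
but kept out of the manifest for exactly this reason).

## Problem sizes

The test suite runs the headline comparison at full scale (7,000 families,
≈20,000 children, ten seeds) and everything else on smaller registries
(300–3,000 families) chosen so each check retains the power it needs; the
acceptance script uses one full-scale registry per seed.
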