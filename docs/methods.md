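# Methods

## Setting and estimand

`gmikit` analyses a single-arm trial cohort in which each patient's own
treatment history supplies the comparator. For a patient whose most recent
prior systemic therapy ended in documented progression, the growth
modulation index

GMI = PFS on the index therapy / TTD on the most recent prior therapy

compares like with like inside one patient: both quantities measure how
long a therapy held the disease. TTD (start to end of the line, any
discontinuation reason) stands in for progression time on prior therapies
because retrospective assessment dates are too sparse to define a true time
to progression; for patients who stopped *because of* progression this
surrogate is tight, which is why the GMI analysis is restricted to the
documented-progression cohort. GMI ≥ 1.3 is the conventional benefit
threshold; 1.5, 1.8 and 2.0 are reported as sensitivity thresholds.

## Cohort classification

Classification reads only the most recent prior line (latest conservatively
imputed end date, ties broken by line number, so the result is
deterministic under partial dates): discontinuation for primary resistance
or progressive disease → documented progression; any other reason
accompanied by a recorded progression date → documented progression;
otherwise → no documented progression; no prior lines → no prior therapy.
Progression documented on an *earlier* line does not qualify — the GMI
denominator comes from the most recent line, and only that line's ending
tells us the therapy failed. A missing discontinuation reason on the most
recent line is a validation error, not a silent default.

## Conservative date imputation

Prior-therapy dates may lack day and/or month components. Missing start
components are filled with the earliest consistent value (1 January / first
of month) and missing end components with the latest (31 December / last of
month), with end dates truncated at the index-therapy start. The imputed
TTD is therefore an upper bound on the true TTD and the GMI a lower bound:
the analysis can only understate benefit. This direction is verified
mechanically (10,000 random masking cases, plus a hypothesis property test
of bracket maximality). A date missing even its year cannot bound anything
and the line is dropped with a logged warning.

Durations convert days to months at the mean Gregorian month, 30.4375
days; the additivity of this conversion is property-tested.

## Survival estimation

The estimators are written from first principles because they are applied
on a nonstandard axis (censored ratios) as well as on time:

- **Product-limit estimator.** At tied times events are processed before
  censorings. Greenwood's formula supplies pointwise variances.
- **Median and CI.** The median is the smallest event time with S(t) ≤ 0.5.
  Its interval inverts the pointwise complementary-log-log band
  (Brookmeyer–Crowley construction, the default family of the standard
  survival packages): the bounds are the first times the lower/upper band
  crosses 0.5, "not estimable" when a band never does. The same machinery
  is used for the KM-of-GMI median CI, as the package's uniform choice.
- **Hazard ratio.** A single-binary-covariate Cox model with the Efron tie
  correction, maximised by damped Newton–Raphson to |Δβ| < 1e-8, Wald CI
  from observed information. A monotone partial likelihood (complete
  separation in time) is flagged (`converged=False`) and reported with an
  infinite bound rather than a spurious number. The PFS-vs-TTD comparison
  puts two outcomes of the same patients into one model; the headline CI
  ignores that pairing (matching the conventional presentation), and a
  leave-one-cluster-out jackknife standard error is available via the
  `cluster` argument for a pairing-aware interval. Both HR directions are
  exported because the ratio's orientation is a frequent source of
  confusion.

Correctness is anchored two ways: an independent brute-force risk-set
product and a dense grid search over the independently coded partial
likelihood (exact / 1e-4 agreement), and cross-checks against lifelines
(agreement to its looser convergence tolerance).

## GMI with censoring

A censored index PFS makes the observed ratio a lower bound. The naive
summary (median, range, inclusive threshold counts) uses face values —
conservative, since a censored patient below a threshold counts as not
reaching it. The censoring-aware analysis runs the product-limit estimator
on the ratio axis; exceedance P(GMI ≥ x) is the left limit S(x⁻), so a
ratio exactly at a threshold counts as achieving it. Two ordering
properties follow and are tested by enumeration: KM exceedance never falls
below the face-value proportion, and the KM median never falls below what
dropping a censored largest observation would give. A prior TTD of exactly
zero (possible after imputation of a same-day line) leaves the ratio
undefined; the patient is excluded from the GMI section with a logged
warning and an entry in the report's exclusion list.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
patient data:

- **Dependence.** A per-patient frailty Z ~ Gamma(mean 1, variance θ)
  multiplies the hazards of both the prior TTD and the index PFS, giving
  frailty-mixed Weibull marginals and Clayton-copula dependence with
  Kendall's τ = θ/(θ+2) — a closed form the tests use as an oracle.
  θ = 0 gives independence. Default θ = 0.5 (τ = 0.2): positive but
  uncertain intrapatient correlation.
- **Marginals.** Weibull shape 1.1 for both endpoints; scales are solved so
  the *marginal* medians under frailty hit 11.2 months (index PFS) and 2.9
  months (prior TTD), the motivating study's toplines.
- **Cohorts.** 71 patients split 38/13/20 by deterministic
  largest-remainder apportionment (a multinomial draw would make
  small-cohort assertions flaky). Documented-progression reasons are drawn
  13:14:11 across primary resistance : progressive disease : other with a
  progression date, mirroring the disposition the cohort definition comes
  from.
- **Calendar.** Enrolment is uniform over a 30-month accrual window from
  November 2015; the administrative cutoff sits at 36 months. Patients
  whose latent discontinuation falls after cutoff are emitted as ongoing
  (TTD censored); PFS is censored at cutoff likewise. Index TTD is latent
  PFS plus an exponential lag (mean 0.5 months), with a 15% chance of
  earlier discontinuation — keeping TTD tracking PFS as the analysis
  presumes. Setting `ongoing_fraction_target` instead places the cutoff at
  the matching quantile of latent end dates (never before the last
  enrolment).
- **Missingness.** Each prior-line date field independently loses its month
  (with the day) with probability 0.10 or just its day with probability
  0.30 — month-precision being the common case in retrospective forms. A
  masked earlier line that would impute past the most recent line's end is
  left unmasked, so imputation cannot reorder a patient's history.
- **Responses.** The index best response is a noisy monotone map from the
  patient's marginal PFS quantile (Gaussian noise σ = 0.22; cuts 0.18 /
  0.40 / 0.97 for PD / SD / PR / CR, 5% not evaluable), yielding responder
  rates near 60% with responders biased toward long PFS. Prior-line
  responses use a coarser map with an 18% unknown rate for the documented
  progression cohort and a fixed categorical mix (no PD, by definition of
  the cohort) for the no-documented-progression cohort.

The `truth` table carries every latent value (frailty, uncensored times,
true unmasked dates), enabling three recovery checks: with masking and
censoring off, pipeline values equal truth exactly; masking never shortens
prior TTD; and on 500-patient lightly censored cohorts the KM exceedance
at each threshold matches the latent-truth Monte Carlo within three
combined standard errors.

What the generator does **not** model: tumour-type-specific survival, CNS
metastasis effects, nonlinear tumour growth kinetics, assessment-schedule
artefacts in progression dates, or any decline of PFS across successive
lines beyond the shared frailty. Passing tests therefore certify the
estimators and the pipeline plumbing, not the clinical realism of any
particular dataset.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for quick, repeatable runs:
Kendall-τ checks use 50,000 pairs (MC error ≈ 0.005), parameter recovery
uses a 500-patient cohort against a 200,000-draw oracle, the
censoring-bias ordering averages 50 seeds of 80-patient heavily censored
cohorts, and conservatism is checked on 10,000 random maskings. Newton
steps are damped to ±2 and an estimate drifting past |log HR| = 25 is
declared divergent. Report JSON rounds floats to 6 significant digits and
contains no timestamps, so identical inputs give byte-identical reports.

## Known limitations

- The GMI rests on the assumption that disease tempo is comparable across
  the two lines; nothing in the package tests that assumption.
- TTD can overrun true progression when patients continue therapy beyond
  progression, biasing GMI downward for prior therapy but upward if used
  on the index arm.
- The naive Wald CI for the PFS-vs-TTD hazard ratio ignores the
  intrapatient pairing; use the jackknife option when that matters.
- Partial-date imputation is intentionally one-sided; cohorts with heavy
  date missingness will see systematically deflated GMIs, which is the
  designed trade-off.
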