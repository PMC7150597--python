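# Methods

## The estimand and the model

The quantity of interest is the mean annual health and care cost per patient
in the five years following a first hospitalisation with atrial fibrillation
(AF), counted under a *global comprehensive* convention: all expenditure of
the cohort is included, whether or not attributable to AF.  Costs are
observed as one row per patient per follow-up year, with a large point mass
at zero (years without any resource contact) and a right-skewed positive
distribution otherwise.  A two-part model separates the two features:

* part one — probit: P(any use | x) = Φ(xβ), fitted on all patient-years;
* part two — gamma GLM with log link: E[y | y > 0, x] = exp(xγ), fitted on
  the positive-cost rows;
* recombination: E[y | x] = Φ(xβ)·exp(xγ).  The reported mean annual cost is
  the *recycled prediction*: this product averaged over the estimation
  sample's covariate rows.

Covariates are ten age bands (0–49 … 90-max, reference 0–49), sex (reference
male), admission year as a centred continuous term, SIMD deprivation quintile
(reference 1, most deprived), the eightfold urban–rural classification
(reference large urban), the 14 health boards (reference Greater Glasgow and
Clyde), a collapsed Charlson comorbidity count (1 = none, 2 = one, 3 = more
than one; reference 1), and 5-year vital status (reference alive), with
age×comorbidity and mortality×SIMD interactions.  Both parts use the same
design.  The alive/dead sensitivity refits filter the panel by vital status
and rebuild the design without the mortality terms.

Both parts are estimated by maximum likelihood (Newton scoring for the
probit, IRLS for the GLM, via statsmodels).  The gamma shape is a nuisance
parameter estimated by moments from the Pearson dispersion (shape =
1/dispersion); the gamma log-likelihood and AIC are evaluated at that shape
with the shape counted as one estimated parameter.  The second-part
specification is compared against OLS on costs and OLS on log costs by AIC;
because a log-scale Gaussian likelihood is not directly comparable with a
cost-scale likelihood, the log-OLS AIC is reported both on the log scale and
with the Jacobian adjustment (+2·Σ log y), and the cross-model selection uses
the adjusted value.

### Diagnostics

Four family/link checks run together on the fitted second part:

1. **Modified Park test** — quasi-likelihood GLM (log link) of squared raw
   residuals on log fitted values; the slope λ estimates the variance power
   Var(y|x) ∝ μ^λ.  λ≈0 points to a Gaussian family, ≈1 Poisson, ≈2 gamma,
   ≈3 inverse Gaussian; the recommendation is the nearest integer's family.
2. **Pregibon link test** — refit on the linear predictor and its square; a
   significant squared term flags link misspecification.
3. **Modified Hosmer–Lemeshow** — F-test that mean raw residuals are zero
   across fitted-value deciles.
4. **Residual–index correlation** — Pearson zero-correlation test between raw
   residuals and the linear predictor.

### Uncertainty

The published interval method for the mean is not recoverable from the text,
so the package's primary interval is a nonparametric percentile bootstrap
that resamples *patients* (not patient-years), preserving the within-patient
correlation of repeated follow-up years.  Each replicate refits both parts
and recomputes the recycled mean on the resampled panel; replicates whose
refit fails (e.g. a resample losing an outcome class) are redrawn up to three
times.  A delta-method alternative (`delta_method_ci`) treats the two parts
as independent and propagates their covariances through the gradient of the
mean; it is model-based and faster but ignores the cross-part dependence.

### Small-sample robustness

With sparse factor levels (small strata, bootstrap resamples) the declared
design can contain empty indicator columns, aliased columns (an interaction
level coinciding with a main effect) or quasi-separated indicators (a level
whose few rows all share one outcome, giving the probit no finite
coefficient).  `fit_two_part` drops such columns and records them in
`dropped_columns`; the strict single-fit functions (`fit_probit`,
`fit_glm_gamma_log`) keep their error contracts.  A panel in which *every*
row has positive cost collapses the model to its second part (the probability
part is identically one); this arises in degenerate test panels and tiny
bootstrap resamples.

## Cohort and costing rules

* **Cleaning** drops exact-duplicate episode rows and rows with unparseable
  dates or discharge before admission, logging counts per reason.  The rule
  set is documented here, not claimed identical to the original extraction's
  unspecified checks.
* **Incidence**: the index event is a patient's earliest admission carrying
  I48 in any of the six diagnostic positions with no I48 admission in the
  preceding five years; one index per patient.  Later AF admissions never
  re-enter as new incidents — a deliberate choice users should be aware of.
  Patients whose index falls within the first lookback window of the extract
  are retained but flagged (`lookback_incomplete`) so a sensitivity exclusion
  is a single filter.
* **Panel**: one row per patient per follow-up year from the index date;
  the year containing death is kept whole (death-year costs are retained as
  observed, not annualised); years entirely after death are dropped;
  `died_within_5y` is death date ≤ index + 5 years.  The patient-year is the
  modelling unit and zero-cost years enter part one as non-users.
* **Comorbidity** is assessed from the diagnoses of the index continuous
  stay (configurable), mapped by ICD-10 prefix to Charlson condition groups
  (Quan coding) and collapsed to the 3-level count.  No weighted index, no
  ICD-9.
* **CIS and spells**: episodes chain into a continuous inpatient stay while
  each admission is within the transfer tolerance (default 0 days: same-day
  transfer) of the running discharge.  Episodes are priced by an HRG-like
  tariff code; within a CIS, for each distinct specialty only the
  highest-cost episode counts and the others contribute zero.  This
  per-specialty-max-over-the-CIS rule is applied as stated, with the spell
  partition available as an intermediate; ties keep a single episode.  A CIS
  is assigned wholly to the follow-up year of its admission date (admission-
  based tariffing); care-home stays, being duration-priced, are apportioned
  day-by-day across years.
* **Currency**: half-up penny rounding at each item; aggregation conserves
  pennies exactly; day counts use half-open intervals (the care-home exit day
  is not costed).
* **Prescriptions** follow the formulaic reading — (item price ÷ pack size) ×
  (quantity × instalments) — rather than any gross-cost field; flagged as an
  interpretation.
* Tariffs are user-supplied lookup tables (total functions: a missing code is
  an error, never zero).  No HRG grouper is included and no inflation
  adjustment is applied.

## The synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any real extract layout.  Covariates are drawn independently from
configurable marginals whose defaults follow the published cohort's baseline
table (sex 50.3% male; health-board, urban–rural, SIMD and comorbidity
proportions; 26.4% 5-year mortality).  Ages follow a truncated normal (mean
74, SD 12.5, range 0–108) discretised into the model's bands, uniform within
band; admission years default to uniform 2005–2012.  β and γ default to the
published coefficient signs and magnitudes with intercepts −1.0 and 7.0;
gamma shape defaults to 1.2 and the sector split to 79/8/7/6%
(inpatient/outpatient/prescribing/care home).  All of these are
configuration, not claims.  An optional `age_comorbidity_assoc` tilts
comorbidity draws by the age z-score so interaction terms have power.

Per patient and follow-up year, any-use is Bernoulli(Φ(xβ)) and positive
totals are gamma with mean exp(xγ); follow-up years are conditionally
independent given covariates (within-patient cost correlation beyond shared
covariates is not modelled — a documented simplification).  Mortality is
generated as the 5-year flag first; the death year is then uniform over the
follow-up and the death date is placed inside the death year after that
year's activity.  Totals are split into sector targets (penny rounding
residual to the largest sector) and materialised as raw records:

* inpatient targets become one CIS of 1–3 episodes in distinct clinical
  specialties with amount-coded tariff codes; with probability 0.3 a
  same-specialty transfer episode with a cheaper tariff code is added, which
  the per-specialty-max rule must zero out;
* the index admission carries I48 in a uniformly chosen diagnostic position
  and secondary codes realising the drawn comorbidity level; when year 1 has
  no inpatient cost the index admission uses a zero-priced tariff so the
  any-use ground truth is preserved exactly;
* outpatient targets become one attendance with an amount-coded tariff;
  prescribing targets one dispensing row whose arithmetic recovers the
  amount exactly; care-home targets an integer number of days at £100 or £50
  per day, with the sub-day remainder folded into the prescribing row so the
  four materialised sectors sum to the drawn total to the penny;
* a burn-in window of non-AF admissions precedes some index dates so the
  lookback is evaluable, and `inject_data_errors` adds exact-duplicate
  episodes with a manifest for measuring cleaner recall.

What passing tests on these data do show: the cohort rules, costing algebra
and two-part estimation recover a truth of exactly the assumed form.  What
they do not show: robustness to miscoding, within-patient cost dependence,
covariate correlation beyond the optional age–comorbidity tilt, informative
censoring, or real tariff structure.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| `lookback_years` | 5 | incident-AF lookback |
| `followup_years` | 5 | follow-up horizon and mortality-flag horizon |
| `transfer_tolerance_days` | 0 | same-day transfer chains a CIS |
| probit `tol` | 1e-10 | Newton gradient tolerance |
| GLM `tol` | 1e-10 | IRLS convergence tolerance |
| `bootstrap_B` | ≥100 (500 typical) | bootstrap replicates |
| `gamma_shape` | 1.2 | DGP cost skewness (variance = mean²/shape) |
| `sector_split` | .79/.08/.07/.06 | DGP sector proportions |
| `dup_rate` | 0.02 | injected duplicate-episode rate in pipeline runs |

Admission year enters as a single continuous coefficient centred at the
cohort's first year.  All randomness flows from one integer seed per run;
generator outputs are bit-identical across runs for a fixed seed.

## Verification design

Simulation-based checks state their conditions explicitly; the problem sizes
are the package's own choices balancing precision against runtime:
recombination against the closed-form oracle on ~52,000 patient-years;
Wald coverage pooled over all coefficient×replicate pairs across 20
replicates of 50,000 patient-years on a reduced design (pooled coverage is
used because a joint "all coefficients in all replicates" criterion has
vanishing pass probability even for a perfectly calibrated estimator, and
per-coefficient 18-of-20 thresholds are themselves coin flips at 20
replicates); AIC family selection over 50 replicates of n=10,000; bootstrap
coverage over 50 outer replicates of 400-patient panels at B=200.  The
probit and gamma fitters are cross-checked against a coarse-to-fine
grid-search maximiser of the same likelihoods — an oracle that shares no
code with the fitting path.

## Known limitations

* Primary-care costs are absent (as in the source data); indirect costs are
  out of scope.
* The generator's years are conditionally independent given covariates;
  panels with strong within-patient cost autocorrelation will make the
  model-based standard errors optimistic — hence the patient-level bootstrap
  default and a cluster-robust option.
* The per-specialty-max rule is applied over the whole CIS; tariffing regimes
  that price repeated same-specialty spells separately need a different rule.
* Stratum refits on small panels may drop sparse factor levels
  (`dropped_columns`); estimates for those levels are then unavailable rather
  than unstable.
* The reporter always derives percentage shares from its own unrounded means;
  published tables whose printed shares disagree with their printed totals
  are reproduced only up to that internal inconsistency (an explicit `total`
  argument supports re-deriving such tables).
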