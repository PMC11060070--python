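# Methods

This note documents the models, rules and numerical choices behind
`nestedcc`: what is simulated, what is estimated, and where genuine design
freedom was resolved by a package-level decision.

## Study design implemented

The analysis is a nested case–control study with incidence-density
(risk-set) sampling inside a cohort of adults with comorbid depression and
newly treated type 2 diabetes.

**Cohort.** Study entry is the date of a patient's first oral antidiabetic
prescription, required to fall at least 183 days after registration (so
that the start of treatment, not a transfer of records, is captured).
Type 2 diabetes is confirmed by at least two glucose tests above a
configurable threshold (default 11.1 mmol/L, the random-plasma-glucose
diagnostic cut-off). Patients whose first insulin prescription comes within
183 days of the first oral agent are excluded as possible type 1 diabetes;
patients whose every antidiabetic prescription falls inside a pregnancy
interval are excluded as possible gestational diabetes. Membership
additionally requires at least one plain depression code dated strictly
after entry; codes specific to dementia, maternity or severe mental illness
never qualify. Whether a pre-entry code alone should qualify is genuinely
ambiguous; the default requires a post-entry code, and
`CohortParams.depression_rule = "any_time"` selects the alternative.
Patients are censored at min(death, deregistration, study end 2018-12-31),
with ties resolved death > deregistration > study end. Exclusions are
tallied by the first failing rule so that input rows always equal excluded
plus retained rows.

**Cases and controls.** Every cohort member with a death strictly after
entry and on or before censoring is a case; its observation period is the
plain calendar-day difference between entry and death. Controls are drawn
uniformly without replacement, up to four per case, from the case's risk
set: members of the same gender and GP practice, entering within ±5 years
of age (inclusive), observed at least as many days as the case, with no
death on or before — and a qualifying depression code on or before — their
pseudo-outcome date (their own entry plus the case's observation days).
Members can serve in several sets and can later be cases themselves.
Requiring the control's depression code *by* the pseudo-outcome date is the
symmetric choice: a case's qualifying codes are necessarily on or before
its death date, so case and control windows carry the same code
opportunity; the any-time alternative is available via
`control_depression_window`.

**Exposure.** Only antidepressant prescriptions with
entry < date ≤ reference date count; a prescription on the entry date is
treated as pre-entry history and one on the reference date as exposure
(deaths are attributable to same-day exposure state). Treatment episodes
pool all agents and bridge successive prescriptions whenever the next one
starts no more than 60 days after the previous prescription's expected end
(date + duration); the episode contributes (last − first) + last duration
days, and episodes sum to the cumulative duration. Recency uses 182 days
exactly; the duration bands use 183/365/730-day cut points (the month-based
band labels are not day-exact in themselves, and these cuts nest with the
182-day recency constant and calendar years). Prescriptions lacking a
recorded duration default to 28 days, the commonest UK repeat-prescription
length. Agent counts compare agent strings case-insensitively. The four
encodings (any, timing, duration band, agent band) must agree on the
exposed/unexposed split; the test suite enforces this as an invariant.

**Estimation.** With exactly one case per set the exact conditional
likelihood is the per-set softmax; no Breslow/Efron tie handling is needed.
Fitting is Newton–Raphson from β = 0 with step-halving on non-increase,
convergence at score sup-norm < 1e-8, at most 50 iterations; the
log-sum-exp in each set is stabilised by its maximum. Monotone likelihoods
(separation) are detected when any coefficient passes 15 in absolute value
and the fit is flagged, not silently reported. Standard errors come from
the inverse observed information, intervals from exp(β ± 1.96·se). Sets
whose rows share identical covariates are non-informative and are dropped
(counted in the result). Columns constant across the whole design are
removed before fitting; matching factors are never entered as covariates.
Categorical exposures are expanded against the no-prescription reference.

**Adjustment set.** All confounders are measured at entry: ethnicity
(missing imputed as white, with a flag), BMI (most recent value on or
before entry; missing imputed by a single seeded draw from a normal fitted
to the observed values — a deliberate simplification of multiple
imputation, bounded by the complete-case sensitivity run), smoking status,
comorbidity flags, diabetes duration proxied as days from first
above-threshold glucose test to entry (the only in-data proxy when entry is
defined at first treatment), primary-care contacts in the prior 365 days,
distinct drug classes in the prior 90 days, and any antidepressant
prescription on or before entry. In the default adjustment list ethnicity
enters as a white/non-white indicator; the finer categories are retained in
the cohort table and the baseline report but are sparse at desk-scale
simulation sizes. Sensitivity analyses re-run matching on the restricted
complete-case cohort, mirroring "include only individuals with complete
data" rather than post-hoc filtering of existing sets.

## The synthetic EHR generator

The generator emulates the *structure* of UK primary-care records — not
demography, code lists or realistic prescribing dictionaries — under a
known causal model, so the pipeline's estimand is a configured constant.

Death times are drawn from a piecewise-constant proportional-hazards model
on the days-since-registration scale:

```
h(t) = baseline_hazard · exp( beta_ad·AD_active(t) + Σ_c beta_c·x_c
                              + beta_age·(age − 65) + severity_link·S )
```

`AD_active(t)` steps from 0 to 1 at the first antidepressant prescription,
`x_c` are comorbidity indicators carried by clinical events, and `S` is a
standard-normal latent severity. Simulation is by a single exponential
waiting time propagated across the exposure change point. Because the
baseline hazard is constant, the conditional-logit odds ratio at matched
event times equals exp(beta_ad) regardless of the time scale offset between
registration and entry. Deaths after deregistration or the study end are
administratively censored, and records dated after death are removed (the
death time itself uses the pre-truncation prescription schedule, which is
equivalent: a first prescription after death implies death occurred
unexposed).

Antidepressant courses form a renewal process starting strictly after the
first oral antidiabetic prescription, with start rate
`ad_course_rate · exp(severity_link · S)` per day; each course is a
geometric-length run of 28-day prescriptions of a randomly chosen agent.
`severity_link` therefore drives prescribing and death *jointly* — the
confounding-by-indication mechanism. Measured confounders (comorbidities,
age) affect the hazard but not prescribing, so with `severity_link = 0`
both the crude and the adjusted analysis estimate `beta_ad`; pre-entry
antidepressant history defaults to zero so that the analysis exposure
window coincides with the hazard's step function. Setting
`p_pre_entry_ad > 0` introduces deliberate exposure misclassification for
robustness experiments.

Defaults (all configurable): 2000-01-01 to 2018-12-31 study period with
registration windows from 1995; baseline hazard 5×10⁻⁵ deaths per
person-day (≈1.8%/year, matching all-cause mortality in an older T2DM
cohort); p(treated T2DM) 0.6; p(depression after entry) 0.75; true log rate
ratio ln 2; comorbidity log hazard ratios 0.5 (cardiovascular) and 0.4
(COPD); age effect 0.05 per year over 65; cause-of-death probabilities
follow the observed case distribution in UK patients with comorbid
depression and T2DM (4.0% endocrine, 31.3% cardiovascular, 28.2% cancer,
15.1% respiratory, 2.6% unnatural, remainder other), drawn independently of
covariates; 30% missing ethnicity and 25% missing BMI. Prescription-pattern
parameters (course start rate 2×10⁻⁴/day, mean five prescriptions per
course, 28-day durations, 90-day oral-antidiabetic refills) are plausible
placeholders: no distributional facts about issue patterns were available
to anchor them, and they are exposed as configuration for exactly that
reason.

Randomness uses one stream per generator stage, spawned from the master
seed; each stage draws a single uniform matrix with one row per patient and
maps columns through inverse CDFs, so enlarging the population leaves
existing patients' records unchanged — a property the tests assert.
Identical (config, seed) pairs reproduce byte-identical tables, and the
whole pipeline is byte-deterministic under a fixed seed.

## What passing tests show — and what they do not

The simulation suite demonstrates, at desk scale on one CPU: unbiased
recovery of the true log rate ratio (50 replicate studies of 5 000
patients, adjusted estimate within ±0.10 of ln 2 with 92–96% interval
coverage), nominal type-I error under the null (100 replicates of 3 000
patients), and a strongly positive crude IRR (≈5–6) when only the
severity link is active — the qualitative confounding-by-indication
signature. Replicate counts and population sizes are the package's chosen
simulation design; the null calibration uses 3 000 patients per replicate
as a deliberately smaller, harder case.

These results validate the *machinery*: the sampling is
exposure-representative of risk sets, the likelihood is maximised
correctly (cross-checked against an independent conditional-logit
implementation and closed forms, and the survival simulation against a Cox
fit), and the estimand algebra is right. They do not validate the
substantive published effect sizes, which derive from confidential
national EHR data: the generator has no realistic age pyramid, practice
structure, code lists, cause-covariate dependence, or informative
deregistration, and real confounding is never limited to a single latent
scalar.

## Known limitations

- Wald intervals only; no robust/sandwich variance, no exact small-sample
  inference. Sparse cause-specific designs at simulation scale often
  separate and are flagged rather than rescued (cause-specific fits are
  therefore opt-in via `AnalysisConfig.causes`).
- BMI imputation is a single stochastic draw, not multiple imputation; the
  complete-case sensitivity run is the guard rail.
- Cause of death is drawn independently of covariates and exposure, so
  cause-specific analyses share one estimand by construction.
- Calendar arithmetic is in integer days throughout; "6 months" is fixed at
  183 days in inclusion logic (a conservative half-year) and at exactly 182
  days in the recency rule, and the two constants are deliberately kept
  separate in configuration.
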