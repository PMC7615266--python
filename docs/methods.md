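# Methods

This note documents the statistical machinery, the synthetic-data model, the
numerical choices, and the limits of what the test suite demonstrates.

## Survival model

Follow-up runs on the time-since-entry scale. Each participant's follow-up is
Lexis-expanded into 5-year age-at-risk bands: one counting-process record
(t_start, t_stop] per band traversed between max(entry age, window start) and
exit, where exit is the earliest of death, the administrative censoring date
(31 December 2020 by default) and the end of the age window. Bands are
half-open [a, a+5). The primary window is ages 35–74 ("premature" mortality,
deaths before 75); the 75–84 window is the same splitter and engine with a
shifted configuration, entering participants at delayed t_start when they
reach 75. Person-time and death counts are conserved exactly by construction,
and the test suite asserts the identity on simulated cohorts.

The hazard for covariates x in stratum s = (sex, band) is
λ_s(t)·exp(xᵀβ): a Cox model stratified by sex and age-at-risk, so the
proportional-hazards assumption is made only within strata. β maximises the
stratified partial likelihood with **Breslow** tie handling (ties are rare on
a continuous timescale; Breslow keeps the independent brute-force oracle
trivial to write). The risk set at an event time t in a stratum is
{j : t_start_j < t ≤ t_stop_j}. Cause-specific analyses recode deaths from
other causes as censorings at the same time (person-time untouched), so the
cause-specific hazards sum to the all-cause hazard and cause-specific event
counts sum to the all-cause count — both asserted in tests.

### Fitting

Risk sums at the E unique event times of each stratum are accumulated by
difference arrays (each record adds exp(xᵀβ) at the first event slot it
covers, removes it after the last), so S0/S1/S2 come from `bincount` plus one
cumulative sum per covariate (pair): O(n·p²) per Newton iteration, no per-risk-
set loops. Newton–Raphson starts at β = 0 with step-halving; steps are
accepted when the log likelihood does not fall by more than a relative slack
of 1e-10·(|ℓ|+1), which is the floating-point noise floor of a sum over tens
of thousands of records. Convergence is declared when the gradient max-norm
falls below 1e-6 and the relative log-likelihood change below 1e-9, **or**
when the Newton decrement gᵀΔ falls below 1e-9·(|ℓ|+1) — an absolute gradient
criterion alone is unattainable at large n precisely because the gradient
inherits that noise floor. Coefficients are capped at ±15; a coefficient at
the cap (a level with no events) raises a separation warning and is flagged
in the results. The covariance is the inverse observed information; exact
duplicate design columns (e.g. the exposure passed again as an adjustment)
are dropped with a warning so nested models remain estimable. Strata with no
events contribute nothing and are dropped. The engine is verified against a
from-scratch pure-Python Breslow likelihood maximised by Nelder–Mead (1e-6
agreement on toy data) and against lifelines' counting-process fitter.
(R's `survival::coxph` agrees on coefficients; its log likelihood differs by
a data-dependent constant because its default `timefix` snaps near-tied
times.)

### Deaths exactly on a band boundary

With half-open bands, a death at exactly age a+5 would belong to the older
band [a+5, a+10) — but its record there would have t_start = t_stop and could
never appear in any (start, stop] risk set, its own event's included. Boundary
deaths therefore close the band they end. The case has probability zero on a
continuous age scale; band indices carry a 1e-6-year slack to absorb float
noise in ages reconstructed from day-precision dates.

## Floated (group-specific) variances

A fitted model reports K−1 log rate ratios against a reference, leaving the
reference without an interval and non-reference comparisons dependent on the
full covariance. The floated variances f ∈ R^K, reference included, solve

    min_{f ≥ 0} Σ_{i<j} (f_i + f_j − C_ij)²,

where C_0j = V_jj and C_ij = V_ii + V_jj − 2V_ij are the model's contrast
variances — a transparent least-squares construction satisfying the
group-specific-CI contract (any-pair comparisons), not a re-derivation of any
particular published floating-absolute-risk estimator. It is exact whenever
an exact non-negative solution exists (diagonal V; any K = 2 problem, where
the underdetermined split is resolved by the minimum-norm equal split), and
the worst-case relative distortion max |f_i+f_j−C_ij|/C_ij is always reported
so a user can see when floating misleads. On realistic five-level education
fits the distortion is well under 1%.

## Mediation by proportional attenuation

Two summaries, both exploratory by nature:

* 100·(1 − χ²_adj/χ²_unadj), where χ² is the likelihood-ratio statistic for
  adding education to a model without/with the mediators;
* 100·(1 − logRR_adj/logRR_unadj) for a chosen contrast (default: none vs
  tertiary) and per level.

Rows missing any mediator (or with unknown diabetes status) are dropped from
*all* nested fits so likelihoods are comparable; nesting (χ² ≥ 0) is asserted.
Continuous mediators (weight, height, waist, hip, SBP) enter linearly;
smoking (5 groups), alcohol (5), activity (3) and diabetes status (5: none,
undiagnosed with HbA1c > 6.5%, diagnosed with HbA1c <9 / 9–<11 / ≥11%) enter
as dummies. Percentages outside [0, 100] (suppression) are reported as
computed. These are attenuation measures, not counterfactual natural
direct/indirect effects, and single baseline mediator measurements understate
long-run exposure. A caveat the package makes measurable: adjusting for
covariates that are education-graded but causally inert still removes a
non-vanishing share of the χ² through collinearity alone (~15% under the
default gradients at n = 100 000), so the χ²-based proportion should be read
against the log-RR attenuation, which stays near 0 in that situation.

## Projection

For each sex and 5-year band with national annual rate N, education
prevalences p and study rate ratios r (reference 1), the calibrated rates are
r_k·A with A = N/Σp_k r_k, making the prevalence-weighted average exactly N
(machine-precision identity, asserted). Distinct RR vectors may be supplied
per age range (e.g. 35–59 and 60–69) or one vector overall. Survival is
piecewise-exponential on the bands; partial life expectancy over [35, 70) is
the exact in-band integral Σ S(a)·(1 − e^{−wλ})/λ (limit w·S(a) as λ → 0),
verified against fine-grid quadrature. Raising one level's RR raises that
level's absolute rates and lowers its partial life expectancy while raising
everyone else's — the calibration redistributes a fixed total, a property the
tests assert. The bundled national life table is a clearly-labelled
**synthetic stand-in** (Gompertz-like rates by sex); projections against it
demonstrate the machinery, not any country's actual survival, and no claim is
made of reproducing published survival percentages or the published
life-expectancy gap, which require the true national life table. Both the
truncated [35, 70) life expectancy and the calibration identity are exact
regardless of the table supplied. No uncertainty is propagated into
projections by default.

## Synthetic-cohort generator

The generator emulates the structure the analysis assumes — it defines the
study conditions for every test and for the acceptance script:

* **Demographics.** 33% men; education distributions per sex default to the
  study's reported ones (male 7/16/24/27/25%, renormalised from printed
  percentages summing to 99; female 13/21/29/25/12%). Entry ages are
  truncated-normal(50.7, 10.8²) on [35, 85); entry dates uniform over
  1998–2004; administrative censoring at 2020-12-31 (mean follow-up ≈ 19.5
  years). Entry age is independent of education — the real birth-cohort
  gradient in education is deliberately not modelled, which age-at-risk
  stratification makes immaterial to the rate ratios.
* **Mediators.** Continuous covariates are Gaussian with education-specific
  means (SBP, adiposity measures and HbA1c decline with education; height
  rises slightly), a sex shift, and floor truncation; categorical covariates
  are multinomial with education-specific probabilities (smoking, alcohol,
  activity); diabetes diagnosis is Bernoulli with prevalence falling from 21%
  to 6% across education. Mediators are conditionally independent given
  education and sex — the dependence structure among mediators is not
  available in published summary form, so only education-conditional
  marginals are modelled; the full joint distribution of the covariates is a
  non-goal.
* **Hazards.** Cause-specific baselines are piecewise-constant on 5-year
  bands, Gompertz-like (doubling per 8 years of age, male rates 1.3×/female
  0.85× a common anchor chosen so that ~9–10% of a study-like cohort dies
  before 75), split across eight cause groups in rough proportion to the
  reported premature-death cause mix (renal & acute diabetic ~20%, cardiac
  ~19%, cancer ~16.5%, ...). Education acts through a direct log-RR per cause
  plus mediator coefficients (SBP 0.022 per mmHg, diagnosed diabetes log-HR
  0.9, smoking and inactivity gradients); preset modes place the whole effect
  directly (`direct_only`), wholly through mediators (`mediated_only`), keep
  mediators flat and inert (`mediator_free`), or switch education off
  (`null`). Event times are drawn by exact inversion of the piecewise-constant
  cumulative hazard; the cause is drawn proportional to the cause-specific
  hazards at the event age. Deaths after the censoring date are returned as
  censored.
* **Reproducibility.** One root seed; each generation stage draws from its
  own spawned substream, vectorised by row index, so a participant's draws
  depend only on (config, seed, row index) and identical configurations give
  byte-identical cohorts.

What passing tests therefore show: the estimators recover the generator's
truth under the generator's assumptions (proportional hazards within bands,
correctly-specified mediator forms, independent censoring). They cannot show
robustness to real-data features the generator omits: misclassified education,
correlated mediator measurement error, cohort effects in education by age,
non-proportional hazards, or linkage error.

## Problem sizes and defaults

Parameter-recovery runs use one 50 000-person cohort (~3 600 premature
deaths) plus 200 replicate cohorts of 5 000 for interval coverage; mediation
calibration uses 100 000-person cohorts; null calibration uses 200 cohorts of
3 000. These sizes give the acceptance quantities stable second-digit
precision while keeping a full run to a few minutes on one CPU. Convergence
tolerances, the ±15 coefficient cap, the 1e-6-year band slack and the 20/40/
60/80 linear-interpolation quintile cut-points (boundary values to the lower
quintile; ties broken low) are fixed as described above. Income bands are
left-closed at 1 500/3 000/4 500 pesos with "no income reported" kept as its
own category, never imputed (it can reflect either high or low socioeconomic
position); income analyses are restricted to men by a sex filter since most
women report no personal income. Exclusions apply in fixed order — age ≥ 85,
missing education, missing-or-extreme covariate (height outside 120–200 cm,
weight 35–250 kg, BMI 15–60 kg/m², waist 60–180 cm, hip 70–180 cm, WHR
0.5–1.5), uncertain linkage — each row counted once against the first rule it
violates, so the ledger reproduces sequential "a further n were excluded"
accounting.

## Known limitations

* Breslow (not Efron) ties only; fine on a continuous timescale, biased if
  times are heavily grouped.
* The floated-variance construction is a documented least-squares surrogate;
  equivalence with specific published floating-absolute-risk estimators is
  out of scope.
* Attenuation-based mediation inherits all the usual caveats (no causal
  ordering, single measurements, collinearity effects quantified above).
* Projections assume the study rate ratios transport to the national
  population and ignore estimation uncertainty unless bootstrapped by the
  caller.
* The generator's defaults are qualitative emulations of published summary
  tables, not a calibrated digital twin of any cohort.
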