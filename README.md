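# mortgap

Educational inequalities in adult mortality, as a tested, reusable pipeline:
age-at-risk stratified Cox rate ratios with floated (group-specific)
confidence intervals, likelihood-ratio mediation attenuation, and calibration
of study rate ratios to national death rates to project survival and partial
life-expectancy gaps by education.

The package is written for epidemiologists and biostatisticians who analyse
prospective cohort mortality by socioeconomic position — specifically the
design in which adults recruited over a calendar window are followed through
death-registry linkage, follow-up is split into 5-year age-at-risk bands, and
premature mortality (deaths before age 75) is contrasted across five education
levels (none, incomplete primary, complete primary, secondary, tertiary).
Because cohort data of this kind are restricted-access, a first-class
synthetic-cohort generator reproduces the statistical structure the analysis
assumes (education gradients in lifestyle and physiological covariates,
proportional cause-specific hazards, administrative censoring), so every stage
is exercisable and testable at desk scale.

## The model

Let λ_s(t) be the baseline hazard in stratum s = (sex, 5-year age-at-risk
band), with t the time since study entry. For covariate vector x (education
dummies against the tertiary reference, plus optional adjustments),

    λ(t | x, s) = λ_s(t) · exp(xᵀβ),

so proportionality is assumed only within strata. β maximises the stratified
partial likelihood with Breslow tie handling; delayed entry within a stratum
is encoded by counting-process records (t_start, t_stop], with risk set
{j : t_start_j < t ≤ t_stop_j} at each event time. Rate ratios are
RR = exp(β); each exposure level — the reference included — receives its own
floated variance f_k ≥ 0 chosen by non-negative least squares so that
f_i + f_j ≈ Var(log RR_i − log RR_j) for every pair, and the achieved
worst-case distortion is reported.

Mediation is quantified by proportional attenuation: the percent change in the
likelihood-ratio χ² for education (and in a contrast's log RR) when education
is added to a model with versus without candidate mediators (smoking, alcohol,
physical activity, weight, height, waist, hip, diabetes status, systolic
blood pressure).

Projection calibrates education-specific absolute rates r_k·A to a national
life table via the anchor A = N / Σ_k p_k r_k per age band (p = education
prevalences, N = national rate), so the prevalence-weighted average reproduces
N exactly, then builds piecewise-exponential survival curves and partial life
expectancy over ages 35–70.

## Worked example

```python
import mortgap as mg

cfg = mg.study_cohort_config(20_000, seed=1)        # study-like generator
cohort = mg.generate_cohort(cfg)
kept, ledger = mg.apply_exclusions(cohort)          # eligibility rules
records = mg.lexis_split(mg.derive_categories(kept), 35, 75)
res = mg.fit_stratified_cox(records, "education")
print(res.summary())
print(res.rr_table().to_string(index=False))
```

prints

```
Stratified Cox proportional hazards (Breslow ties, delayed entry)
records: 80919   events: 2330   loglik: -16579.6612   LR chi2 vs null: 122.46
converged: True in 4 iterations (max |score| = 1.11e-10)

term                                log RR        SE      RR              95% CI
education=none                      0.7776    0.0837   2.176      (1.847, 2.564)
education=primary_incomplete        0.6707    0.0753   1.956      (1.687, 2.267)
education=primary_complete          0.5016    0.0733   1.651      (1.430, 1.906)
education=secondary                 0.3467    0.0751   1.414      (1.221, 1.639)

             level       rr    lower    upper  n_events
              none 2.176335 1.950937 2.427773       327
primary_incomplete 1.955554 1.798410 2.126429       548
  primary_complete 1.651391 1.529232 1.783310       648
         secondary 1.414429 1.300044 1.538877       539
          tertiary 1.000000 0.885635 1.129133       268
```

Reading the output: 20 000 simulated participants yield 80 919 person-band
records and 2 330 deaths before age 75. Participants with no education have
2.18 times the premature death rate of those with tertiary education (the
generator's default settings place a direct plus a mediated education effect
on every cause of death). In the rate-ratio table every level, including the
tertiary reference (RR fixed at 1), carries its own floated 95% CI, so any
two levels can be compared by eye. The same objects drive mediation
(`mg.mediation_analysis(records)`) and projection
(`mg.EducationProjection(...)`).

A command-line interface mirrors the library:

```
mortgap simulate --n 20000 --seed 1 --out cohort.csv
mortgap fit --cohort cohort.csv --cause all --age-range 35-74 --out fitdir
mortgap mediate --cohort cohort.csv --cause all
mortgap project --rr 1.8,1.75,1.6,1.35,1
mortgap run --config configs/demo.yaml
```

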