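# jointrisk

Personalised outcome prediction for hip and knee replacement surgery.

Patients considering a joint replacement face three questions: *how much
better will I feel*, *what is my risk of dying soon after surgery*, and *how
likely is it that the new joint will need to be replaced*. `jointrisk` is
the computational engine for answering them from a patient's own attributes
(age, sex, BMI, ASA grade, pre-operative questionnaire score, surgery type).
It is aimed at biostatisticians building and validating such decision-support
models: it provides model fitting, a coefficient-bundle registry, the
end-to-end per-patient calculation, a repeated cross-validation harness, and
a synthetic cohort generator so the whole pipeline can be exercised without
access to confidential registry data.

## The models

**Survival (mortality and revision).** Both events are modelled with a
flexible parametric proportional-hazards model (the Royston–Parmar family).
The cumulative hazard for covariates *x* is

    Λ(x, t) = Λ₀(t) · exp(βx)

and the baseline is a natural cubic spline in log time,

    log Λ₀(t) = γ₀ + γ₁·log t + Σⱼ γⱼ₊₁·νⱼ(log t),

where the νⱼ are restricted-cubic basis functions: piecewise cubic with
continuous second derivative, linear beyond the boundary knots. With no
internal knots (m = 0) the model is exactly Weibull. β and γ are estimated
jointly by maximising the right-censored log-likelihood. Death and revision
are treated as cause-specific processes: when fitting one, the other is
recoded as censoring at its observed time. Event probability is
1 − exp(−Λ(x, t)); the headline outputs are mortality within 1 year and
revision within 10 years.

**PROM score.** The post-operative patient-reported outcome measure (an
integer questionnaire score, default range 0–48) is a linear regression on
the pre-operative score, age, age², and further covariates, fitted by
ordinary least squares; predictions are rounded and clamped to the score
range.

**Filters.** Before fitting, records are excluded when incomplete or outside
accepted clinical ranges: ASA grade must be 1–3, age in [30, 100] years,
BMI in [15, 55] kg/m², with a per-record reason code.

**Validation.** 50 repetitions of fivefold cross-validation; metric values
are averaged over folds, then over repetitions, with a 95% confidence
interval across repetitions. Metrics: RMSE (PROM), Harrell's concordance
index and a fixed-time Brier score (survival).

## Worked example

```bash
# generate a 2000-patient synthetic cohort and the models that produced it
jointrisk simulate --n 2000 --seed 5 --out cohort.csv --truth-out truth.json

# personalised calculation for one patient
jointrisk predict --bundle truth.json --format text \
    --field age=68 --field sex=female --field bmi=29 \
    --field asa=2 --field surgery_group=hip --field prom_pre=18
```

prints

```
Predicted post-operative PROM score: 35
Mortality risk within 1 year:  0.82%
Revision risk within 10 years: 4.04%
```

i.e. this patient is predicted to reach an Oxford-style score of 35 out of
48, with a 1-in-122 chance of death within a year of surgery and a 4%
chance of needing a revision within ten years. `--format json` returns the
full year-by-year curves. Cross-validate a model on a cohort table with

```bash
jointrisk validate --input cohort.csv --model mortality --reps 50 --k 5 --seed 1
```

The same operations are available as library functions
(`jointrisk.fit`, `jointrisk.fit_prom`, `jointrisk.calculate`,
`jointrisk.repeated_cv`, `jointrisk.simulate_cohort`, ...).

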