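# Methods

## Survival model

Mortality after surgery and revision of the implant are modelled separately
as cause-specific time-to-event processes under a flexible parametric
proportional-hazards model. The cumulative hazard is
Λ(x, t) = Λ₀(t)·exp(βx), with covariates entering log-linearly. The baseline
is a restricted (natural) cubic spline in y = log t:

    s(y) = γ₀ + γ₁ y + Σⱼ γⱼ₊₁ νⱼ(y),
    νⱼ(y) = (y − kⱼ)₊³ − λⱼ (y − k_min)₊³ − (1 − λⱼ)(y − k_max)₊³,
    λⱼ = (k_max − kⱼ)/(k_max − k_min).

This basis is cubic between adjacent knots, has a continuous second
derivative everywhere, and is linear outside the boundary knots
(identically zero below k_min), which prevents the wild tail behaviour of
unconstrained cubics when extrapolating risk beyond the observed follow-up.

**Scale convention.** By default the spline represents the *log* cumulative
hazard, log Λ₀(t) = s(log t) (`scale="log"`). An additive convention in
which Λ₀(t) = s(log t) literally is available (`scale="identity"`) but is
not the default: the additive form cannot guarantee a positive, monotone
cumulative hazard for arbitrary γ, so it is only a valid probability model
on a restricted parameter set. On the log scale any γ yields a positive
baseline, and monotonicity reduces to s′ > 0, which is checked after
fitting on a 100-point grid over the observed time range (violations are
reported as a diagnostic flag and a warning, not silently corrected).

**Knots.** The number of internal knots m is configurable (default 2, a
common choice balancing flexibility against stability for registry-sized
data; m = 0 gives a Weibull model). Boundary knots sit at the minimum and
maximum observed log *event* times, internal knots at the equally spaced
quantiles of log event times between them. Inside cross-validation, knots
are re-derived from each training fold so no information about held-out
event times leaks into the fit. Events falling exactly on a boundary knot
are evaluated by the same formula — it is defined there — with no special
casing.

**Likelihood and fitting.** With right censoring, the log-likelihood is
Σᵢ [dᵢ log h(tᵢ|xᵢ) − Λ(xᵢ, tᵢ)], where under the log convention
h(t|x) = Λ(x, t)·s′(log t)/t. β and γ are estimated jointly by BFGS with
the analytic gradient

    ∂ℓ/∂β = Xᵀ(d − Λ),   ∂ℓ/∂γ = Dᵀ(d − Λ) + D′ᵀ(d/s′),

where D and D′ are the spline design and its derivative. γ is initialised
by least squares from a Nelson–Aalen-type crude cumulative-hazard estimate
evaluated at the event times (log-transformed under the log convention),
and β at zero; this start is deterministic, so refitting the same data
reproduces parameters bit-identically. Parameter vectors that give any
event a nonpositive hazard receive a large negative sentinel likelihood
(−1e10), which the line search backs away from. Convergence requires a
gradient norm below 1e-8 (up to 500 iterations); on failure a Nelder–Mead
restart from the best iterate is polished by BFGS once more, and persistent
failure raises an error carrying the last iterate. Ties in event times need
no correction — this is a fully parametric continuous-time likelihood, not
a partial likelihood. Follow-up times must be strictly positive; zero
durations are rejected rather than offset. Time is in years throughout.

**Competing events.** Death while modelling revision (and vice versa) is
recoded as censoring at the event time *before* the data reach the
likelihood, treating the two processes as independent. The resulting
quantity is a cause-specific cumulative risk, 1 − exp(−Λ); with dependent
risks it can overstate the crude (real-world) probability of the event, a
known property of the censoring convention that users comparing against
cumulative-incidence estimates should keep in mind. If both events are
recorded at the identical time, the target event counts as observed — the
conservative choice for the event being modelled.

## PROM model

The post-operative PROM score is regressed on the pre-operative score, age,
age² and further covariates by ordinary least squares. The quadratic age
term captures the curvature of recovery with age without stepping outside
the linear-model framework. An intercept is included by default (a
no-intercept flag exists; an interceptless score regression forces the
regression through zero, which is rarely what one wants on a bounded
score). The instrument is treated as an opaque bounded integer score with
default range [0, 48] (the Oxford Hip/Knee Score convention); range and
direction carry no semantics inside the package. Predictions are rounded
half-up and clamped to the range; half-up is arbitrary but least surprising
when scores are displayed to patients. Rank-deficient designs are rejected
with the collinear columns named (identified by pivoted QR).

## Filters

ASA grade ∈ {1, 2, 3}, age ∈ [30, 100] years, BMI ∈ [15, 55] kg/m², all
bounds inclusive — boundary patients are clinically valid. Completeness is
checked first, then ASA, age, BMI; the first failing rule fixes the reason
code, so per-reason counts partition the rejected records. The required
field list defaults to the community covariates plus the pre-operative
score and can be overridden per model bundle. No imputation is attempted.

## Calculator

A model bundle packages the (PROM, mortality, revision) triple with a
shared covariate schema, keyed by surgery group (hip, total knee,
patellofemoral, unicompartmental), model type (community = self-reportable
inputs only; clinic = adds surgical-choice covariates that a professional
enters), and dataset version (latest = lexicographically greatest string).
Community bundles are structurally forbidden from containing clinic-only
covariates. Bundles serialise to JSON with explicit coefficient arrays —
for a clinical tool the coefficients must be auditable by eye — and a
format-version field that fails loudly on unknown versions; floats survive
the round trip bit-exactly. The per-patient calculation validates the
request against the same ranges as the cohort filters (reporting every
failing field at once), then evaluates the PROM prediction and both risk
curves at years 1–10. Headline values are mortality at year 1 and revision
at year 10; the ten-year horizon for both curves is a display choice, not a
model constraint.

## Cross-validation

`repeated_cv` runs R repetitions (default 50) of k-fold (default 5)
cross-validation with a fresh random partition per repetition; fold sizes
differ by at most one. The per-repetition metric is the mean over folds;
the overall estimate is the mean over repetitions with a 95% CI from the
normal approximation across repetition means (percentile bootstrap
optional). A repetition in which any fold fails is excluded and counted;
more than 20% failures aborts the run. Concordance uses Harrell's
definition restricted to usable pairs (the earlier time has the event) with
score ties counted 0.5 — on tie-free continuous times this coincides with
the standard implementation in lifelines, which the tests verify against,
alongside an exact O(n²) brute-force oracle. The Brier score takes
outcomes already resolved at the horizon; no inverse-probability-of-
censoring weighting is applied, so records censored before the horizon must
be excluded by the caller.

## Synthetic cohorts

The generator draws covariates independently within the filter bounds —
age ~ N(68, 10²) truncated to [30, 100], BMI ~ N(29, 5²) truncated to
[15, 55], ASA 1/2/3 with probabilities 0.15/0.65/0.20, 58% female,
surgery-group mix 43.2/51.1/5.0/0.7% (hip/total/uni/patellofemoral),
pre-operative score ~ N(18, 8²) rounded and clipped — and simulates death
and revision times from two independent proportional-hazards truths by
inverse transform: u ~ U(0, 1), solve Λ(x, t) = −log u (closed form for
Weibull truths, Brent root-finding on the monotone spline otherwise).
Administrative censoring applies at 12 years; the observed record carries
min(T_death, T_revision, censor) with both indicators, matching what a
registry extract looks like under the cause-specific convention. The PROM
outcome is the linear truth plus N(0, 4²) noise, rounded and clamped. The
default truths give ≈0.7% baseline one-year mortality (hazard ratios ≈2.2
per decade of age, 0.74 female, 1.6/2.7 for ASA 2/3) and ≈4% baseline
ten-year revision risk decreasing with age — plausible magnitudes for an
arthroplasty population, chosen once as fixture defaults.

Because events are generated from the same family the fitters estimate,
passing recovery tests demonstrates correctness of the estimation machinery
*under its own assumptions* — not robustness to real-data features the
generator omits: correlated death/revision processes (frailty),
informative censoring, covariate measurement error, non-proportional
hazards, or registry-scale covariate distributions.

## Problem sizes in tests

Recovery tests run at n = 5000 (bias checks also at n = 500 against
n = 5000), the cross-validation protocol at its full 50×5 size on a
2000-record cohort, and Monte-Carlo oracles at 10⁵–10⁶ draws; these sizes
make sampling error comfortably smaller than the asserted tolerances while
keeping the default suite fast.
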