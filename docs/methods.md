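# Methods

## Scope and data model

`imtrial` analyses two-arm trials whose primary outcome is a weekly symptom
total formed from a 7-day daily diary, collected once at baseline (run-in)
and once at week 4 (study days 22–28).  A participant record carries both
diaries with explicit per-day missingness, the enrollment order, the
eligibility flag (total baseline count at least 3), the arm, and — for
synthetic data — the latent ground truth used by tests.  The long diary CSV
format is one row per participant-phase-day with an empty count cell meaning
a missing day, never zero.

## Synthetic-data generator

Daily baseline counts are Poisson with log-rate `β₀ + u_i`,
`u_i ~ Normal(0, σ_u²)`; week-4 days add a secular trend `β_trend` common to
both arms and the treatment effect `β_treat` in the immediate arm.  Defaults:

| parameter | default | reason |
|---|---|---|
| `β₀` | log 2 | baseline weekly median 7·exp(β₀) = 14 |
| `σ_u` | 0.6 | reproduces the baseline IQR of roughly 9–20 |
| `β_trend` | log(10/14) | the control arm also improves: week-4 median ≈ 10 |
| `β_treat` | −1.9 | multiplicative effect exp(−1.9) ≈ 0.15 on week-4 rates |
| `missing_rate` | 0.005 | sporadic missing diary days (a few per hundred) |
| `loss_rate` | 0.095 | pre-randomisation withdrawal/loss, matching a CONSORT flow in which ~9 of 95 eligible participants never reach randomisation |
| eligibility floor | 3 | screening rule: fewer than 3 baseline IMs excludes |

Missingness is completely at random (MCAR); the per-day masking call is a
separate stage so missing-at-random variants can be injected by callers.
Ineligible and lost participants are generated and flagged, not dropped, so
CONSORT tallies are testable against the generator's own bookkeeping.

What the generator does *not* emulate: per-day serial correlation beyond the
shared participant intercept, heavy-tailed outlier participants, informative
missingness, or dropout after randomisation.  Two visible consequences:
(1) the synthetic ineligibility fraction (~0.5%) is lower than a real
population's, because the lognormal lower tail is thin; (2) Cohen's d on
synthetic week-4 totals comes out around 1.2–1.6 rather than the 0.85 a
noisier real-data SD produces — the pooled SD here lacks the extreme
outliers that inflate it in practice.  Passing tests therefore demonstrate
correctness of the machinery under the stated data-generating process, not
robustness to every real-data pathology; the sensitivity suite (priors,
negative-binomial family, outlier and imputation exclusions) is the tool for
probing the latter.

## Imputation

Missing diary days are imputed before weekly totals are formed, with a
stationary Gaussian AR(1) on the transformed scale `y = log(count + 1)`:

```
y_t − μ = φ(y_{t−1} − μ) + e_t,   e_t ~ N(0, σ²_e),  |φ| < 1.
```

Parameters are pooled across all series of a phase and estimated by
expectation–maximisation.  The E-step is an exact Kalman filter/RTS smoother
(the diary observes the state without noise, so observed days collapse the
state variance to zero and missing days simply skip the measurement update);
the smoother also yields the lag-one covariances the M-step needs.  The
M-step updates `μ` in closed form given `φ` and then profiles `(φ, σ²_e)`
with a bounded 1-D maximisation of the expected complete-data log-likelihood
— an ECM scheme, so the observed-data log-likelihood is non-decreasing by
construction (asserted in tests).  Convergence: absolute log-likelihood
change below 1e-6, cap 200 iterations; non-convergence sets a flag and warns
rather than raising, because a usable imputation is still returned.

Missing cells are filled with their conditional expectation given the
observed days, back-transformed, and rounded to the nearest non-negative
integer (diary counts are integers).  Imputation is a single deterministic
fill, not multiple imputation; the sensitivity suite's
imputation-exclusion variant quantifies its influence.  On complete data the
stage is a no-op.  The transformed-scale conditional mean back-transforms
with a small downward bias for large gaps (no lognormal variance
correction); with the default missingness of half a percent this is
negligible, and the rounding absorbs most of it.

## Primary analysis model

Week-4 daily counts are repeated Poisson observations sharing a participant
rate (this repetition is what identifies a participant random intercept):

```
y_ij ~ Poisson(λ_i),  log λ_i = β₀ + β_base x_i + β_treat T_i + u_i,  u_i ~ N(0, σ_u²),
```

`x_i` the standardised baseline weekly total, `T_i = 1` for the immediate
arm.  The weekly total is the sufficient statistic, so the likelihood is a
Poisson on `7λ_i` and the random intercept is integrated out per participant
by adaptive Gauss–Hermite quadrature (20 nodes, integrand re-centred at its
mode by Newton steps — accurate for both tiny and large counts).  This
reduces inference to a 4-parameter marginal posterior.

Priors: Normal(0, 2.5) on `β₀, β_base, β_treat` (standardised covariate
scale) and Half-Normal(1) on `σ_u`.  These are deliberately weakly
informative; the sensitivity suite shows the posterior is
likelihood-dominated at the trial's size, so moderate prior changes move the
treatment-effect posterior mean by well under 0.3.

Sampling (`method="mcmc"`): an adaptive independence Metropolis–Hastings
sampler in the unconstrained space `(β₀, β_base, β_treat, log σ_u)`.  A
Laplace fit (BFGS with batched finite-difference gradients, central-difference
Hessian) seeds a pilot chain; the proposal is then moment-matched to the
pilot draws and used as a two-component multivariate-t mixture (df 4, scales
1.1× and ~10×, weights 0.8/0.2) so posterior tails stay covered and chains
cannot stick.  Defaults: 4 chains × (300 burn + 1500 kept) draws.  Split-R̂
and ESS come from ArviZ; a fit is only summarised when all R̂ ≤ 1.01, and the
run is automatically extended (doubled, at most twice) if the gate is missed.
Summaries are posterior means with equal-tailed 95% credible intervals; the
rate ratio is exactly `exp` of the posterior mean.  `method="laplace"` skips
the chain and samples the matched normal directly — used by the sequential
monitor and the operating-characteristic simulations, where thousands of
fits are needed.

Model checking: posterior predictive p-values (mid-p convention, so discrete
statistics such as the zero-count fraction stay calibrated) for the mean,
variance and zero fraction of weekly totals per arm.  Outlier detection
combines marginal Pearson residuals (Poisson-lognormal mean and variance, so
a participant is compared with their arm-and-baseline peers rather than
with their own fitted intercept, which would absorb the anomaly) with
Cook's distance and leverage from a fixed-effects Poisson GLM approximation
(statsmodels); a flag requires a large residual plus a large influence
measure, with all thresholds configurable.  A negative-binomial family
switch (sum of 7 iid NB days is NB with 7× mean and shape) supports the
model-variation sensitivity analysis.

## Directional Bayes factors and sequential monitoring

Hypotheses are one-sided on `β_treat` against the point null:
a *positive* (beneficial) effect is `β_treat < 0` (fewer IMs), a *negative*
(harmful) effect is `β_treat > 0`.  The default estimator is the one-sided
Savage–Dickey ratio from the encompassing fit,

```
BF(H_dir : H₀) = [p(0 | prior) / p(0 | posterior)] × [P_post(dir) / P_prior(dir)],
```

with the marginal posterior of `β_treat` summarised either by a normal
approximation (default — exact for the Laplace path, fast, and accurate
whenever the posterior is not many SDs from 0) or by a Gaussian kernel
density on the draws (`density="kde"`, preferable when evidence is strong
and the tail shape matters).  Bridge sampling (`method="bridge"`) estimates
the marginal likelihoods of the encompassing and null models directly
(Meng–Wong iteration with a moment-matched multivariate-normal bridge
proposal; the null model is refitted with `β_treat = 0`) and serves as the
independent cross-check: on small datasets the kde-based Savage–Dickey and
bridge estimates agree to a few tens of percent, which is the scale of both
estimators' Monte-Carlo error.

The monitor walks the completion-ordered stream: first look at 20
completers, then every 4 (or an explicit schedule), final analysis at the
150-participant ceiling.  At each look the harm check runs first; only if
`BF_negative` stays below the threshold (20) is `BF_positive` computed — the
harm check is a gate, not a symmetric race.  Either BF above threshold stops
the trial (`stop_negative` / `stop_positive`); the full trace is always
returned for audit.

## Operating characteristics

`simulate_trial_once` composes generation → screening → minimisation
randomisation (66% preferential to the smaller arm, 85% from the 62nd
randomised participant onward, ties by fair coin) → outcome generation →
MCAR masking → EM imputation → sequential monitoring, with one RNG
substream per replicate so results are independent of execution order.
`operating_characteristics` aggregates exact multinomial decision
proportions and the sample-size-at-decision distribution;
`bf_vs_n_curve` reports the BF distribution at fixed sample sizes for
prospective planning.  Because planning effect sizes are usually quoted as a
standardised mean difference, `effect_from_cohens_d` bridges d to a log-rate
effect by simulating weekly totals over a grid of `β_treat` values and
interpolating the standardised difference to the target (the mapping depends
on the generator's heterogeneity, which is why it is a routine and not a
formula).

Default replicate counts in the test suite and acceptance script (200 for
calibration checks, 100 per operating-characteristic estimate, reduced grids
for curves) were chosen so the whole suite runs on a single CPU in well
under half an hour while keeping Monte-Carlo error a small fraction of each
asserted margin; all are parameters, not constants.

## Numerical choices and degenerate inputs

- Eligibility screening counts missing baseline days as zero (an unreported
  day cannot qualify a participant).
- A participant is "analysed" with ≥ 4 of 7 observed week-4 days (remaining
  days imputed); configurable, and rarely binding at the default missingness.
- Quantiles use linear interpolation between order statistics (this is the
  convention under which an IQR like 6–16.5 arises from integer data).
- Cohen's d is computed on raw week-4 weekly totals (unadjusted for
  baseline) with a noncentral-t confidence interval; `nct` tail underflows
  far from the observed statistic are replaced by their limits.
- The AR(1) innovation variance is floored at 1e-10 so constant series
  (e.g. all-zero diaries) degrade gracefully; `|φ|` is bounded at 0.999.
- Posterior evaluations clip the linear predictor at ±30 so absurd proposals
  yield −inf rather than NaN, which the MH step simply rejects.
- `σ_u = 0` is handled as a pure Poisson likelihood (no quadrature), making
  the fixed-effects limit exact.

## Known limitations

- Single deterministic imputation understates imputation uncertainty; with
  more than a few percent missing days a multiple-imputation wrapper would
  be appropriate.
- The Savage–Dickey normal path loses accuracy when the posterior is far
  from the null (evidence overwhelming); decisions are insensitive to this —
  any estimator agrees the threshold is crossed — but reported extreme BF
  magnitudes should be read as orders of magnitude, and the kde or bridge
  estimator preferred for them.
- The generator's Poisson-lognormal tails are lighter than real diary data;
  standardised effect sizes computed on synthetic data run larger than their
  real-data counterparts at the same rate ratio.
- Minimisation uses group size only (as in the trial); no covariate
  stratification is implemented.
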