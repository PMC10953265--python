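# Methods

This note records the models the package implements, the numerical choices
behind them, what the simulator does and does not emulate, and the design
decisions taken where more than one defensible option existed.

## Models and estimands

Outcome: `logit P(Y=1 | A=a, M=m, C=c) = θ0 + θ1 a + θ2 m + θ3 a m + θ4'c`.
Mediator: Gaussian `M = β0 + β1 a + β2'c + ε`, `ε ~ N(0, σ²)` (continuous),
or `logit P(M=1 | a, c) = β0 + β1 a + β2'c` (binary). Estimands are the
conditional natural direct, indirect and total effect odds ratios for the
1-vs-0 exposure contrast at fixed covariates `c`; identification needs the
usual consistency, positivity and sequential-ignorability conditions, which
the package takes as given.

**Exact estimators.** The nested counterfactual probability
`P(Y(a, M(a*))=1 | c)` is the mediator-model average of
`expit(θ0 + θ1 a + θ2 m + θ3 a m + θ4'c)`. Binary mediator: a two-term sum.
Continuous mediator: a logistic-normal integral with no closed form,
evaluated by Gauss–Hermite quadrature (below). Effects are ratios of odds
of these probabilities; `TE = NDE × NIE` holds by construction.

**Approximate estimators.** Under a rare outcome the odds in the estimand
approximate the probabilities and the integral acquires a
moment-generating-function closed form, giving the familiar expressions
(continuous: `NDE = exp(θ1 + θ3(β0 + β2'c + θ2σ²) + θ3²σ²/2)`,
`NIE = exp(β1(θ2 + θ3))`; binary: ratios of `1 + exp(·)` factors). These
are printed for a 0/1 exposure only, and the package rejects other
contrasts for them; the exact estimators accept any two exposure levels.

**Design strategies.** Under outcome-dependent sampling the naive mediator
fit is biased whenever the mediator predicts the outcome, and the naive
outcome intercept is shifted by ≈ `logit(p) − logit(π)` (p = sample case
fraction, π = population prevalence). Corrections: fit the mediator model
on controls only (valid as a rare-outcome approximation); weight both
models by π/p (cases) and (1−π)/(1−p) (controls); or maximise the joint
prospective likelihood

```
Π_i  P(M=m_i | Y=0, a_i, c_i) · θ(a_i, m_i, c_i)^{y_i} / (1 + θ(a_i, c_i))
```

where `θ(a,m,c)` is the conditional outcome odds and `θ(a,c)` its average
over the control-stratum mediator law (closed MGF form for a Gaussian
mediator, two-term sum for a binary one). The unified likelihood needs no
user-supplied π but models the control-stratum mediator distribution with
the population-model form, i.e. it also leans on the rare-outcome
approximation. The approximate intercept shift means approximate effects
are intercept-free, so only the mediator-model correction matters for them;
the exact effects involve θ0 directly, which is why the exact approaches
require the weighted outcome fit as well.

## Numerical choices

- **Weighted GLM fits** use `statsmodels` (IRLS, coefficient tolerance
  1e-8, 100 iterations max). For the weighted linear model,
  `σ² = Σ w e² / (Σ w − k)` (weighted ML with a degrees-of-freedom
  correction). Non-convergence, divergence (|coef| > 50) and perfect
  separation raise a typed `ConvergenceError`; the benchmark harness logs
  and excludes such replicates and reports `n_reps_used`.
- **Coefficient covariance.** Unit-weight fits use the model-based inverse
  information. For unequal (IPW) weights the model-based covariance of the
  weighted pseudo-likelihood is badly miscalibrated — it treats the
  reweighted sample as a rare-outcome cohort and overstates the intercept
  SE several-fold (empirically ~5× against the replicate SD). The default
  under IPW is therefore the estimating-equation sandwich `A⁻¹BA⁻¹` with
  `B = Σ w_i² s_i s_i'`, which reproduced near-nominal delta coverage in
  calibration runs; `cov_type="model"|"sandwich"|"auto"` exposes both.
- **Quadrature** for the logistic-normal integral: Gauss–Hermite centred at
  the mediator mean, scaled by σ√2, starting at 64 nodes with doubling
  until successive values agree within 1e-8 (512-node cap, then a typed
  error). Nodes are cached per order.
- **Unified maximisation:** BFGS on `(θ, β, log σ)` with an analytic
  gradient, started from the naive outcome fit and the controls-only
  mediator fit (both consistent under the rare-outcome approximation);
  convergence requires max |score| < 1e-4, with one jittered restart before
  failing. The joint covariance is the inverse observed information,
  computed by central differences of the analytic gradient with step
  `1e-5·(1+|coef|)`; the (θ, β) block of the inverse is used downstream.
- **Overflow control:** all odds are handled on the log scale
  (`logaddexp` / `log_expit`); counterfactual probabilities within 1e-12
  of 0 or 1 raise rather than being clipped, surfacing degenerate fits.
- **Delta method:** central finite-difference gradient of the log-OR with
  step `1e-6·(1+|coef|)` against the joint (θ, β) covariance; σ is held
  fixed at its estimate (its sampling variability is ignored, as in the
  standard closed-form variance treatments). Intervals are symmetric on the
  log scale; level defaults to 0.95.
- **Bootstrap:** percentile intervals from order-statistic quantiles;
  resampling is stratified on the outcome by default, preserving the
  design's fixed case:control split (unstratified via flag); failed
  replicates are dropped and counted, >50% failures aborts. Sub-seeds
  derive deterministically from the configured seed.
- **Conditioning covariates** default to sample means, matching common
  package behaviour; under case-control sampling these do not converge to
  the population means, so `conditioning="ipw-means"` offers IPW-corrected
  means when π is available. Scenario truths use the analytic population
  means (E[C1] = c1_prob, E[C2] = 0).

## Simulator and bundled scenarios

The generative model: `C1 ~ Bernoulli(c1_prob)`, `C2 ~ N(0, c2_sd²)`
independent; exposure `A ~ Bernoulli(expit(−0.5 + 0.1 C1 − 0.15 C2))`;
mediator from the mediator model (Gaussian noise SD σ, or Bernoulli);
outcome from the outcome logistic model. Balanced samples take n/2 cases
and n/2 controls without replacement. The implied marginal prevalence has
a deterministic nested-quadrature form (`marginal_prevalence`); conditional
prevalences by mediator quartile or exposure×mediator cell are Monte-Carlo
(`scenario_prevalence`).

Replicate draws in the benchmark harness use a *fresh*, adaptively sized
population per replicate (expected cases ≥ 1.5× the requested number,
doubling on a short draw). Sharing one finite population across replicates
leaves a common sampling offset of order sd/√(population cases / sample
cases) — about 3% on the OR scale in the rare scenarios — which a
replicate-level summary would misreport as estimator bias.

Six bundled scenarios span three prevalence regimes per mediator type:
rare everywhere (~0.7–1.4% in every stratum), rare-to-moderate marginally
(~8–9%) but common (~20–25%) in high-mediator strata, and common
(~33–35%). Coefficients were chosen to realise those regimes (checked via
the prevalence functions) with moderate, epidemiologically plausible
effect sizes; the implied true effects are computed, never asserted. The
regimes separate the estimators as expected: under rarity every approach
is nearly unbiased; under conditional commonness only the exact IPW
estimator keeps small bias for all three effects, the approximate-IPW
total effect degrades by >20% (continuous case), and the unified approach
tracks the controls-only approximate approach.

What the simulator does *not* emulate: covariate-matched or frequency-
matched controls, incidence-density sampling, measurement error,
missingness, non-Gaussian continuous mediators, or exposure-covariate
interactions. Passing benchmarks therefore speak to estimator behaviour
under clean unmatched case-control sampling with correctly specified
models, not to robustness against those features.

The `ccmediate.demo` module generates a fully synthetic case-control
dataset with marginals styled after an ovarian-cancer / oral-contraceptive
mediation analysis (364 cases / 907 controls, protective exposure, strongly
exposure-suppressed continuous mediator). It exists to demonstrate the API
on realistic-looking inputs; it is not calibrated beyond those marginals.

## Benchmark conventions

Bias = mean − truth; SD uses the n−1 denominator; RMSE is computed from
replicate-level squared errors, so `rmse² = bias² + sd²·(reps−1)/reps`
(the identity is tested). Coverage is the percent of replicate intervals
containing the truth, reported separately for delta and bootstrap
intervals and as missing when intervals are absent or degenerate. The
prevalence-misspecification sweep runs the IPW approaches at
`π(1+r)` over r ∈ {−99%} ∪ {−95%, …, +100% step 5%} (points with π ≥ 1
skipped with a warning); the prevalence-free approaches are constant in r
and reported once for reference. At r = −99% case weights in the mediator
model are nearly null, so the IPW mediator fit collapses to the
controls-only fit — the controls-only strategy is the implicit π → 0
endpoint of the sweep.

Default problem sizes: n = 1000 samples, 200–500 replicates in the shipped
analyses (each entry of the acceptance JSON records its own `n`), 1000
bootstrap resamples for user-facing intervals and 100–200 inside nested
benchmark loops. These sizes hold Monte-Carlo noise on relative biases to
a few tenths of a percent, comfortably below the effects of interest.

## Known limitations

- The delta-method variance treats σ̂ as fixed and uses numeric gradients;
  no closed-form variance expressions are provided.
- The unified fit's observed information is finite-difference based;
  profile-likelihood intervals are not offered.
- The controls-only and unified strategies inherit the rare-outcome
  approximation for the mediator model; their mediator coefficients are
  biased when the outcome is conditionally common (visible in the
  benchmark scenarios).
- IPW results are only as good as the supplied π; the sweep exists
  precisely because π is rarely known exactly.
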