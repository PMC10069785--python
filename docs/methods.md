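# Methods

## Model

Responses `y_i` follow a regression model `f_Y(y | x; β)` fitted by maximum
or penalised likelihood.  A subset of covariates is observed only through
`W = X + U` with classical additive error `U ~ N(0, Σᵤ)`, `Σᵤ` known
(squared covariate units; diagonal unless a full matrix is supplied).  The
structural prior on the latent covariate is multivariate normal,
`X ~ N(μ_x, Σ_x)`.  Error-free covariates need no distributional
assumptions and pass through untouched.

The target is the observed-data likelihood, with `X` integrated out.  The
EM Q-function is approximated by importance sampling from the error
distribution: `B` imputations `x̃⁽ᵇ⁾ = w − ũ⁽ᵇ⁾` are drawn once and kept
fixed for the whole run.  Because the proposals come from `f_U`, the
`f_W(w|x)` factor cancels from the weights, leaving
`q_i⁽ᵇ⁾ ∝ f_Y(y_i|x̃_i⁽ᵇ⁾; β) f_X(x̃_i⁽ᵇ⁾)`, normalised over `b` for each
observation (observations are independent, so the joint weight factorises).
The M-step maximises the weighted complete-data (penalised) likelihood on
the `nB` stacked rows — the literal "replicate the responses B times"
construction, so any weighted fitter can be plugged in unchanged.

Conditional on the fixed imputations, the procedure is an exact EM over
`(β, μ_x, Σ_x)` jointly: the prior update (importance-weighted mean and
covariance of the imputations, each value carrying mass `q_i⁽ᵇ⁾/n`) is
itself an exact M-step for the normal prior parameters, so the Monte-Carlo
observed log-likelihood ascends every iteration.  The ascent property is
asserted in the tests with tolerance 1e-6.

### Observed log-likelihood and ESS

The reported log-likelihood is the Monte-Carlo marginal
`ℓ̂ = Σᵢ log{(1/B) Σ_b f_Y f_X}` — equivalently the Q-function minus the
weight entropy (both routes are computed and cross-checked to 1e-8).  Note
it includes the marginal density of the observed noisy covariate; for
capture–recapture AIC comparisons against conditional-likelihood fits this
marginal term is subtracted so all models are scored on the `(y | w)` scale
(at `σᵤ² = 0` the corrected AIC equals the naive one exactly).

The per-observation effective sample size `ESS_i = 1/Σ_b (q_i⁽ᵇ⁾)²`
(range `[1, B]`) diagnoses the prior-as-proposal approximation.  It decays
as the error variance or the number of contaminated covariates grows; both
trends are asserted as regression-slope sign checks in the test suite.

### Standard errors

The Louis decomposition of the observed information is evaluated in its
Monte-Carlo form from analytic exponential-family scores and Jacobians
(canonical links: `s_i = (dℓ/dη) x_i`, `J_i = (d²ℓ/dη²) x_i x_iᵀ`), with
conditional expectations replaced by importance-weighted averages over the
imputations.  The covariance is solved through a QR factorisation of the
information (never an explicit inverse); condition numbers above 1e12
trigger a warning, and a non-positive-definite information raises with the
advice to increase `B` (Monte-Carlo error is the usual cause).  Wald
intervals use the normal quantile at the requested level (default 95%).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `B` | 50 | Monte-Carlo imputations; SE stability needs roughly B ≥ 50 |
| `epsilon` | 1e-5 | stop when `max|Δβ| / (1 + max|β|)` falls below it |
| `max_iter` | 100 | iteration cap; exceeding it flags `converged=False` with a warning |
| `seed` | — | single RNG seed governing the imputation draws; fitters are deterministic |
| `update_prior_each_iter` | True | re-estimate `(μ_x, Σ_x)` by weighted moments each iteration; set False to fix a known prior |
| `ci_level` | 0.95 | Wald interval level |

Prior initialisation is the moment correction `μ_x = mean(w)`,
`Σ_x = cov(w) − Σᵤ`, with eigenvalues floored at `1e-6 · trace` to keep the
density proper when the difference is indefinite.

## Fitters

* **GLM** — gaussian-identity, binomial-logit, poisson-log, fitted by IRLS
  (statsmodels backend) with frequency weights implementing the prior
  observation weights; cross-checked in tests against an independent Newton
  maximiser of the weighted log-likelihood.  Gaussian dispersion is
  re-estimated by the weighted Pearson statistic after each M-step (it
  enters the E-step densities) and held fixed in the Louis information at
  convergence.
* **GAM** — penalised weighted IRLS written in-package: cubic B-spline
  bases on *equally spaced* knots over a range expanded 30% beyond the
  observed data (so imputations stay inside the basis support; the
  padding is per-term configurable via `s(x, k=.., expand=..)`), an
  order-2 coefficient-difference penalty, and a sum-to-zero centering
  constraint for identifiability next to the intercept.  Equal knot
  spacing is deliberate: it makes the penalty null space exactly the
  linear-in-x trend, so infinite smoothing collapses to the linear GLM.
  Knots and constraints are computed once from the observed data and
  frozen, keeping coefficients comparable across EM iterations.  Smoothing
  parameters are selected by GCV on every weighted refit by default
  (`select_lambda="fixed"` freezes them, and is what the EM-ascent
  guarantee strictly requires, since re-selection changes the objective
  between iterations).  The penalty Hessian `λS` joins the Jacobian term
  of the Louis information, giving Bayesian-style band covariances.
* **Positive binomial** — the zero-truncated conditional likelihood for
  closed-population capture–recapture with occasion-constant individual
  capture probabilities, fitted by damped Newton iterations with analytic
  gradient and Hessian (verified against finite differences).  Spline
  capture effects reuse the P-spline machinery; the smoothing parameter is
  chosen by AIC on the naive fit and frozen during MCEM.

## Point processes

The Berman–Turner device turns the Poisson point-process likelihood into a
weighted Poisson GLM: quadrature points at the raster cells with weight
`|A|/n` (their sum is checked against the window area), presences appended
with weight `ε = 1e-6` and pseudo-response `1/ε`.  The intercept-only fit
recovers `λ̂ = m/(|A| + mε)`, indistinguishable from `m/|A|` on
landscape-scale windows.

For measurement error, the latent covariate is attached to the **raster
cell**: a presence shares its nearest cell's single error draw and
importance weight (the generic `groups` argument of `run_mcem`).  This is
both what the data structure implies — the raster is measured once per cell
— and a mathematical necessity: treating every presence's covariate as
independently contaminated makes the marginal likelihood unbounded in the
slope (each presence row's latent tilt contributes `β²v/2` while the
quadrature void terms are bounded below), which we confirmed numerically as
estimates that grow with `B`.  With cell-level grouping the corrected slope
bias is small and shrinks as `B` grows.  Covariates are attached by
nearest-cell lookup; windows are rectangles, with `|A|` taken from the
geometry.  Scenario prediction shifts a named covariate additively before
evaluating `λ̂(s) = exp{x(s)'β̂}`.

## Capture–recapture

Inclusion probabilities `π_i = 1 − (1 − p_i)^τ` feed a Horvitz–Thompson
estimate; under MCEM, `N̂ = Σᵢ Σ_b q_i⁽ᵇ⁾/π̂_i⁽ᵇ⁾`.  The variance is a
Huggins-type reconstruction — the conditional-capture term
`Σ (1 − π̂)/π̂²` plus a delta-method term pushing the Louis coefficient
covariance through `∂N̂/∂β` — since no canonical closed form is imposed by
the estimator itself.

## Synthetic data

The generators define the package's study conditions:

* quadratic logistic design — `logit P(Y=1) = 0.5 + X − 0.3X²`,
  `X ~ N(0,1)`, `n = 800`, error `U ~ N(0, σᵤ²)`; the tracked quantity is
  the quadratic coefficient (−0.3), the term most attenuated by noise;
* smooth Poisson design — `log μ = cos(2X + 1/4)` for the GAM machinery,
  with held-out prediction RMSE on the linear predictor (both the literal
  mean-squared quantity and its square root are reported; tables use the
  root), optionally under a +0.5 covariate shift that punishes attenuated
  fits;
* robustness designs — `(χ²₃ − 3)/6` (the literal scaling, variance 1/6;
  a `standardize` flag divides by √6 for unit variance instead, since
  either convention is defensible) and a two-piece skew normal with
  `κ = 3` sampled as `κ|Z|` with probability `κ²/(κ²+1)`, else `−|Z|/κ`.

Every generator is deterministic given `(seed, rep_index)`.  The study
harness reports relative bias, RMSE and empirical 95% Wald coverage per
method and error variance, logging and excluding replicate-level failures.

What the synthetic designs do **not** emulate: correlated measurement
errors across covariates, heteroscedastic or non-normal error, spatially
correlated contamination of rasters, and unknown `Σᵤ`.  Passing tests
therefore certify the algorithmic correction under the stated error model,
not robustness to mis-stated error structure (the robustness designs probe
only the latent-covariate distribution).

## Numerical choices

* Importance weights in log scale with per-row max subtraction; an
  observation whose every imputation underflows raises an explicit error
  naming the row rather than returning NaN.
* Convergence metric `max|Δβ| / (1 + max|β_old|)`; stable for coefficients
  near zero.
* Step-halving line searches keep both penalised IRLS and the
  positive-binomial Newton ascent monotone.
* `(1−p)^τ` computed via `exp(τ log1p(−p))`; inclusion probabilities are
  clipped away from 0 before inversion, and a HT estimate with `π̂ ≲ 1e-8`
  is refused as unstable.
* Test problem sizes are the package's own study sizes: the benchmark
  simulation uses 100 replicates (bias/coverage conclusions are stable at
  this size), and the large-sample consistency check contrasts
  `(n=400, B=40)` with `(n=1600, B=100)` over 15 replicates.

## Known limitations

* Sampling from the prior is expected to degrade beyond a few contaminated
  covariates; monitor the reported ESS.
* Validity rests on `Σᵤ` being known and the normal structural prior being
  adequate; the robustness designs show the correction degrades gracefully
  but measurably under skewed latent covariates.
* Point-process support is v1-scoped: rectangular windows, nearest-cell
  covariate lookup, independent cell-level contamination (no spatial error
  correlation model).
* No SIMEX, Bayesian, mixed-model, survival or ordinal support; σᵤ
  estimation from replicate measurements is out of scope.
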