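# Methods

## Model

The inverted exponentiated Rayleigh (IER) distribution has

* pdf  f(x; θ, λ) = 2θλ x⁻³ [1 − e^{−λx⁻²}]^{θ−1} e^{−λx⁻²}
* cdf  F(x) = 1 − [1 − e^{−λx⁻²}]^θ
* reliability R(x) = [1 − e^{−λx⁻²}]^θ, hazard H(x) = f/R,
  cumulative hazard −θ ln(1 − e^{−λx⁻²})

for x > 0, with shape θ > 0 (the exponent) and scale λ > 0 (inside the
exponential).  The quantile function is closed form,
x = √(−λ / ln(1 − (1−u)^{1/θ})).  The upper tail decays like x^{−2θ}, so the
model has heavy tails for small θ and no moments of order ≥ 2θ; the hazard is
upside-down bathtub shaped.

Everything is evaluated in log space.  The recurring factor
`log(1 − exp(−t))` with t = λx⁻² uses an `expm1`/`log1p` split
(`log(−expm1(−t))` for t ≤ ln 2, `log1p(−exp(−t))` otherwise), which keeps
powers θ in the hundreds — as arise when fitting the bundled data — accurate,
and keeps all objective functions finite for t up to ~700.  The quantile's
inner logarithm uses the same helper, so cdf/quantile round trips hold to
1e−10 across the unit interval.

## Censored sampling

`CensoringPlan(n, m, R₁..R_m, T)` describes the design; the three one-point
removal patterns of the study (`scheme1/2/3`: all n−m spares removed at the
first, middle ⌈m/2⌉, or last failure) are provided as constructors.
Progressive Type-II samples use the uniform-spacings construction
(vᵢ = τᵢ^{1/(i + Σ_{j≥m−i+1} Rⱼ)}, Uᵢ = 1 − Π v, Xᵢ = F⁻¹(Uᵢ)), indexed by
the full planned m — the hybrid truncation at min(X_m, T) is applied
afterwards, which is what "generate an ordinary progressive Type-II sample,
then stop the clock" means operationally.  A failure exactly at T (a
probability-zero event) counts as observed; a sample with zero failures
before T raises `EmptySampleError` rather than being silently redrawn — the
study harness redraws and counts.

## Maximum likelihood

The shape has the closed-form profile θ̂(λ) = r / Q(λ) with
Q(λ) = −[Σ(1+Rᵢ) ln(1 − e^{−λxᵢ⁻²}) + R_T ln(1 − e^{−λC⁻²})] > 0, so the fit
reduces to a bracketed Brent root solve of the profiled score in λ
(multiplicative bracket expansion around λ₀ = median(x)²·ln 2, xtol 1e−12),
with a Nelder–Mead search in (ln θ, ln λ) as fall-back when no sign change is
found.  Convergence is declared from the score norm at the solution.  The
observed information is closed form (verified against numeric Hessians at
1e−4 relative tolerance in the tests); its inverse feeds
normal-approximation intervals (ACI-NA, est ± z·se — lower bounds may go
negative and are deliberately not truncated) and log-normal intervals
(ACI-NL, exp(ln est ± z·se/est)) as the positivity-respecting alternative.
R(x) and H(x) estimates are plug-ins (invariance); their variances come from
the delta method with closed-form gradients.

## Maximum product of spacings

The objective sums log cdf increments between consecutive ordered failures
(conventions F(x₀) = 0, F(x_{r+1}) = 1) plus the same survival-power terms
for removed units as the likelihood, with exponents θRᵢ and θR_T.  With
Lᵢ = ln(1 − e^{−λxᵢ⁻²}), the i-th spacing factors as
exp(θL_{i−1})·mᵢ, mᵢ = −expm1(θ(Lᵢ − L_{i−1})) ∈ (0, 1], and all gradient and
Hessian terms are formed as ratios in which exp(θL) cancels — a naive
difference of two nearly equal cdf powers loses up to half the mantissa when
λx⁻² is large, which is exactly the regime heavy censoring produces.  The
analytic gradient and observed information are verified against finite
differences.

Tied observations (the relief times are recorded to 0.1 h) give zero
spacings; each tied spacing is replaced by the density f(xᵢ; θ, λ) — the
standard remedy — with matching density derivatives in the gradient and
Hessian so the optimizer sees a consistent objective.  The optimizer is
L-BFGS-B in log-parameters (bounds ±40, i.e. e^{±40}) with a Nelder–Mead
fall-back, the same initialization as the MLE, and the MPS observed
information supplies covariances for ACIs exactly as in the likelihood
route.

## Bayesian estimation

Independent gamma priors in rate form (prior means a/b for θ, c/d for λ;
"near-noninformative" means all four hyperparameters 0.001).  The θ full
conditional is exactly Gamma(a + r, b + Q(λ)) — Q is the same profiled
factor as in the MLE.  The default sampler is the Metropolis–Hastings-
within-Gibbs scheme: normal random-walk proposals for both parameters,
proposal scales equal to the MLE asymptotic standard deviations times a
tuning factor (default 1), chain initialized at the MLE, proposals ≤ 0
rejected outright.  Because the θ conditional is conjugate, a second sampler
(`run_gibbs_theta`) draws θ exactly and is used as an independent
cross-check: both samplers must agree within Monte-Carlo error, which is the
module's primary correctness gate (they do, and both agree with 2-D
quadrature of the posterior on the bundled data).

Defaults: 12 000 iterations / 2 000 burn-in in simulation contexts, 50 000 /
10 000 for the real-data report; LINEX asymmetry values (−2, +2) in
simulation, (−3, −0.03, +3) in the report — all overridable.  Point
estimates: posterior mean (squared error) and −(1/a)·ln E[e^{−aξ}] (LINEX,
computed by log-sum-exp; a → 0 recovers the mean, and Jensen's inequality
orders LINEX(a>0) ≤ SE ≤ LINEX(a<0)).  Intervals: equal-tailed quantile
intervals (type-7 linear interpolation) and HPD intervals as the shortest
window of ⌊level·M⌋ draws over the sorted chain.  Posterior summaries report
mean, Gaussian-KDE mode (512-point grid), quartiles, SD (n−1) and moment
skewness.

## Monte-Carlo harness

`SimulationDesign` defaults encode the study conditions: truth
(θ, λ) = (0.4, 0.8), T ∈ {1.5, 2.5}, (n, m) ∈ {(40, 20), (40, 32), (80, 40),
(80, 64)}, all three schemes, 1000 replicates, mission time 0.5 (the design
point has R(0.5) = 0.9834913, H(0.5) = 0.2175712), informative priors
(2, 5, 4, 5) and (4, 10, 8, 10) whose means equal the truth.  Each cell
draws samples from a per-cell seeded stream (replicates with zero failures
before T are redrawn and counted), fits MLE and MPS with ACI-NA intervals,
optionally Bayes with HPD intervals, and aggregates APE (mean estimate),
RMSE, MRAB (mean |error|/truth), ACL (mean interval width) and CP (coverage
percent), with the Monte-Carlo standard error of each APE reported so
reduced-replicate runs can be compared honestly.  The test suite and the
acceptance script run single cells at 150–500 replicates; the full grid is a
configuration choice (`ierph study --config ...`), not a default.

The goodness-of-fit check is the one-sample Kolmogorov–Smirnov statistic
with the p-value from the asymptotic Kolmogorov distribution of √n·D,
treating the fitted parameters as known.  No estimated-parameter (Lilliefors
type) correction is applied — the plug-in convention is the one the bundled
analysis uses; its p-values are therefore optimistic and should be read as a
descriptive fit index, not a calibrated test.

## What the generator does and does not emulate

The synthetic-data engine reproduces the exact stochastic mechanism of the
study design: iid IER lifetimes, deterministic removal plans, hybrid
truncation.  It does not model random (e.g. binomial) removals, inspection-
time rounding (real relief times are recorded to 0.1 h, which is why the
bundled data contain ties and simulated data do not), covariates, or model
misspecification.  Passing tests therefore certify the estimators under the
model's own assumptions; robustness to rounding enters only through the MPS
tie rule.

## Known limitations and deliberate choices

* The real-data tables this package reproduces print the fitted pair in
  transposed order relative to the density's parameterization; the package
  keeps the parameterization of the density (θ = exponent) everywhere and
  documents the mapping where results are compared.
* Censored-sample standard errors from the observed information are larger
  than some published counterparts for the bundled data; the implementation
  here is the one that matches numeric Hessians and the complete-data case,
  and the tests pin that behaviour.
* The M-H sampler is a plain random-walk scheme; no adaptation, no formal
  convergence diagnostics beyond acceptance rates (the conjugate-Gibbs
  cross-check is the correctness instrument).  Heavy posteriors (small r,
  flat shape direction) mix slowly; raise `n_iter` or `proposal_factor`.
* `fit_mle`/`fit_mps` require r ≥ 2; degenerate samples raise.
* K-S p-values are plug-in (see above).
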