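# Methods

## Model

CATS regression treats a single site's abundance vector over S species as
the response of a GLM whose predictors are species traits and whose offset
carries the meta-community expectation. Fitting a model with and without
that offset, and with and without traits, quantifies the relative roles of
local trait selection and regional (dispersal-driven) structure.

Supported response families, in exponential-family form
`f(y) = exp{[y*psi - b(psi)]/a(phi) + c(y, phi)}`:

| family | mean domain | variance | auxiliary (fixed) |
|---|---|---|---|
| gaussian | R | sigma2 | sigma2 |
| poisson | (0, inf) | mu | — |
| binomial | (0, n) | mu(1 - mu/n) | n |
| negbin | (0, inf) | mu + mu^2/theta | theta |
| tweedie (1<p<2) | (0, inf) | phi mu^p | p, phi |
| trunc_poisson / trunc_negbin | (0, inf) | (of the untruncated base) | — / theta |

Auxiliary parameters are constants of a `Family`; the distributions belong
to the exponential family only when theta and p are known, so estimation
(profile ML for theta; p is always user-supplied) lives in the fitting
layer. All deviances are scaled deviances `D* = 2[l(full) - l(mu)]`;
every R² is a ratio of deviances and is invariant to the scaling.

Saturated likelihoods use analytic limits at boundary observations
(`y ln y -> 0` at y = 0; for zero-truncated families the per-observation
supremum at y = 1 is the degenerate point mass, contributing 0, and for
y > 1 it solves truncated-mean = y by bracketed root search).

The Tweedie density (compound Poisson–gamma) is evaluated as a
Poisson-weighted series of gamma densities in log space, with the index
range centered on the dominant term and extended adaptively until terms
fall 40 log-units below the maximum (relative tail < 1e-15). The series is
validated in tests against numerical integration (unit mass, mean = mu)
and against the closed-form Tweedie deviance.

## Offsets

* Log link: `O_i = ln(pi_i)`; any additive constant is absorbed by the
  intercept, so using `ln(mean abundance)` instead changes nothing.
* General link: `O_i = h(pi_i * y_tot)` (the arbitrary constant is fixed by
  taking `O_1 = h(pi_1 * y_tot)`). With the *canonical* link of the fitted
  family and an intercept, the score equation forces the fitted total to
  equal the observed total, which makes the intercept-only fit reproduce
  `mu_i = pi_i * y_tot` and hence the prior exactly. With a non-canonical
  link this guarantee disappears — the motivation for recommending the log
  link generally, since `exp(beta_0 + O_i) = e^{beta_0} pi_i` reproduces
  prior ratios under *any* intercept value.
* Domain failures (logit with `pi_i * y_tot >= 1`) raise a structured
  error naming the offending species; an explicit `fallback="log-prior"`
  mode reproduces the pragmatic field practice of using `ln(pi)` under the
  chosen link, with a warning that prior reproduction is then only
  guaranteed under a log link.
* Zero-prior species are flagged on the `MetaPrior` and rejected at offset
  construction rather than given -inf offsets: the model cannot represent
  structural absence in the prior, and silent infinities corrupt the
  optimizer. How to treat species present locally but absent regionally is
  genuinely open; exclusion-with-error is this package's documented choice.
* Hurdle offsets: presence frequencies give log offsets for the binomial
  part; the truncated part uses `ln(m~)` where `m~` solves
  `m+ = m~/(1 - exp(-m~))` (Poisson; negbin analogue with known theta) by
  Brent root search on a bracket guaranteed by monotonicity (absolute
  tolerance ~1e-12). No solution exists for `m+ <= 1`.

## Fitting

Fisher scoring (IRLS) with step-halving handles every family/link pair
with the standard mean structure, canonical or not — the same policy as
mainstream GLM implementations, so a separate quasi-Newton path for
non-canonical links would add surface without adding capability. Two cases
get dedicated treatment:

* **Log-binomial** (relative-risk regression): the ML estimate often sits
  near the boundary `mu = n`, where IRLS steps exit the domain. The
  likelihood is maximized by SLSQP under the linear constraints
  `eta_i <= ln(n) - 1e-7`, from a feasible start (intercept at the mean
  presence, slopes zero). Boundary solutions are flagged and returned
  without covariance. A 20-random-start constrained oracle in the test
  suite confirms the single-start fit attains the optimum.
* **Zero-truncated families**: the truncated likelihood is not of IRLS
  form in mu, so coefficients are found by BFGS on the exact likelihood,
  warm-started from the untruncated counterpart's IRLS fit, with a
  Nelder-Mead polish if BFGS stalls on the domain-penalty plateau.

Negative-binomial dispersion is estimated by alternating IRLS at fixed
theta with bounded one-dimensional profile maximization of theta at fixed
means (the glm.nb scheme). Estimates above 1e5 are reported at the cap
1e6 with a "Poisson-like" warning: the profile has no finite optimum when
the sample shows no overdispersion. The theta of the evaluated model is
stored and reused for the null and saturated likelihoods in R²
computations, which keeps nested deviances comparable (at the price that
adding a predictor can occasionally lower R² through a shifted theta).

Traits are centered and scaled by default so slopes are comparable across
sites; recovery of a generating slope in original units requires
`standardize=False`, which simulation-based tests and the acceptance
script use. Predictor count k for the adjustment counts traits only,
never theta/phi/p.

## R² conventions

* Default null: intercept-only, *without* the offset, even for offset
  models. Keeping the offset in the null would force the offset-only
  model's R² to zero, destroying the direct measure of the meta-community
  effect; that convention remains available (pass the offset model itself
  as the null) for comparison.
* Negative R² is reported as-is: it is the proportional *change* in the
  KL distance between observations and predictions, and a prior that
  increases that distance is a finding, not an error.
* The bounded alternative `1 - K(y;mu)/[K(y;mu)+K(mu;mu0)]` evaluates
  `K(mu; mu0)` through the psi/b form (normalizers cancel), treating the
  fitted means as pseudo-observations. It is not defined for truncated
  families, whose cumulant mean is the truncated rather than the location
  mean.
* The randomization adjustment permutes trait-matrix *rows jointly*,
  preserving trait covariance — the conservative reading of "reshuffling
  trait values". With the intercept-only null, the k-penalty cancels in
  the numerator difference, so the raw and penalized numerator variants
  coincide; both are exposed.
* Adjusted partition components are differences of individually adjusted
  R² values (k for trait models, 0 for offset-only), which keeps the
  component identities exact and the four components summing to one.
  Components are not truncated at zero for reporting.

## Synthetic data

The generators define the package's study conditions:

* `simulate_example1` — 50 plots, 20 species, `y ~ NegBin(exp(0.5 x),
  theta=1)`, `x ~ N(10, 3)`: strongly overdispersed counts spanning
  several orders of magnitude in the mean. Used to show biased inference
  (deceptively narrow Poisson CIs) under family misspecification.
* `simulate_example3` — 50 species, expected total A = 2500, standard
  normal traits, `log lambda = a + log pi + s t` with
  `a = log A - log sum(pi exp(s t))`, making `sum(lambda) = A` exact for
  any selection strength s; the prior defaults to a flat Dirichlet draw
  (a neutral choice — the partition's qualitative behavior is also
  checked under a lognormal-weight prior), replicate counts in tests are
  100 at s = 0 and 15 per s in sweeps, sized for stable Monte-Carlo SEs
  at interactive runtimes.
* `simulate_presence_absence_fixture` — a synthetic stand-in for a real
  97-species x 52-site presence/absence survey: right-skewed occupancies
  (beta(0.35, 1.3)) with a few near-ubiquitous species and lognormal site
  quality, so that common species at rich sites violate
  `pi_i * y_tot < 1` and exercise the logit-offset failure path.

What these generators do *not* emulate: spatial autocorrelation among
sites, species interactions (abundances are conditionally independent
given traits), trait measurement error, and priors estimated from few
plots. Passing tests therefore demonstrate correctness of the estimators
under the stated sampling models, not robustness to those field
realities.

## Numerical choices

* IRLS convergence: relative log-likelihood change < 1e-12, max 200
  iterations, 60 halvings per step before declaring failure (with the
  iteration trace attached to the error).
* Root searches (truncated-mean inversion, saturated truncated fits):
  Brent with xtol 1e-12.
* Diagnostic residuals: for discrete families, uniform draws on the exact
  pmf interval `(F(y-1), F(y)]`; Tweedie uses quadrature of the series
  density plus the zero mass; clipping at 1e-12 from {0, 1} guards the
  normal quantile. Anderson–Darling at the conventional 5% level is the
  automated stand-in for visual QQ inspection.
* AIC: `-2 loglik + 2(k + 1 + [theta estimated])`; ties prefer Poisson.

## Known limitations

* Single-site fits only; no shared coefficients across sites, no spatial
  or phylogenetic random effects, and no inference corrections for
  non-independence.
* Tweedie: log link only, p fixed by the user, phi entering through the
  family specification; no p estimation.
* Zero-inflated (mixture) offsets are out of scope — they would require a
  regional estimate of the structural-zero probability, which field data
  rarely support; hurdle models cover the excess-zero case.
* Binomial general-link offsets follow the n = 1 (presence/absence)
  convention `h(pi_i * y_tot)`; for n > 1 construct offsets on the
  proportion scale.
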