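# Methods

## The problem

Quantitative assays have a lower limit of detection (LOD): below it a
measurement is reported only as "undetectable".  For HIV viral load on
the log10 copies/mL scale — the motivating application — this produces a
left-censored continuous outcome, often alongside a high-dimensional
binary predictor matrix (presence/absence of drug-resistance mutations)
with p comparable to or exceeding n.  `bjlasso` fits L1-penalized linear
models to such data without discarding or naively substituting the
censored observations.

## Model

The latent outcome follows a Gaussian linear model

    Y_i = b0 + X_i' beta + eps_i,    eps_i ~ N(0, sigma^2) iid,

observed through the Tobit rule Z_i = max(Y_i, LOD_i) with censoring
indicator delta_i = I(Y_i > LOD_i).  Detection limits are per-row; a
constant LOD is the special case of a constant vector.  The penalized
objective is fixed throughout as

    ||z* - b0 - X beta||_2^2 + lambda * ||beta||_1

— a plain sum of squares with no 1/(2n) factor, an unpenalized
intercept, and the penalty acting on standardized predictors (coefficients
are mapped back to the original scale for reporting).  Any delegated
solver using the 1/(2n) convention is wrapped with the exact mapping
alpha = lambda/(2n); the warm-started path solver calls the
coordinate-descent kernel directly with its 1/2||.||^2 scaling
(l1 weight = lambda/2).

## Buckley-James iteration

Both estimators alternate imputation of censored values with a penalized
refit:

* **Gaussian:** censored rows are replaced by the truncated-normal
  conditional mean E(Y | Y <= LOD_i, X_i) = mu_i - sigma*phi(a_i)/Phi(a_i),
  a_i = (LOD_i - mu_i)/sigma.  The Mills ratio is evaluated via
  log-densities (`scipy.special.log_ndtr`) so rows censored many sigmas
  from the linear predictor stay stable; the closed forms are verified
  against 40-digit quadrature to 1e-8 over a in [-8, 8].
* **Non-parametric:** the data are flipped to the right-censored scale
  (subtract from M = max z, the smallest admissible constant, chosen to
  minimize numeric range), residuals from the current fit are given a
  Kaplan-Meier distribution (events precede censorings at ties; a
  censored maximum is treated as an event so jump masses sum to one), and
  each censored residual is replaced by the KM conditional mean above its
  own value.  A residual at or above the largest jump falls back to that
  largest (tail-corrected) jump, and to its own threshold if the curve is
  empty; either way back-mapped imputations satisfy z* <= LOD.

**Variance update (Gaussian).**  After each refit,

    sigma^2 <- (1/n) [ sum_unc (z_i - mu_i)^2
                     + sum_cens ( Var(Y | Y <= LOD_i) + (z*_i - mu_i)^2 ) ]

with the truncated-variance term Var = sigma^2 (1 - a h - h^2),
h = phi/Phi.  This is the EM-style update: with it the whole loop is a
generalized EM algorithm for the L1-penalized censored-Gaussian
likelihood, so the penalized likelihood ascends monotonically and the
iteration converges smoothly in practice (per-iteration coefficient
changes decay geometrically).  An `"uncensored"` option (residual
variance on uncensored rows only) is kept for sensitivity analysis.  A
consequence worth stating plainly: implementations of censored-Gaussian
Buckley-James that omit the truncated-variance term, use inexact inner
solves, or re-tune lambda inside the loop can cycle between parameter
values; this implementation essentially never terminates through the
oscillation detector, and the detector exists as a guard, not as a
routinely-exercised path.

**Stopping.**  The loop stops when max|d beta| (standardized scale),
|d sigma^2| and max|d z*| all drop below their tolerances (defaults 1e-4,
on the order of cross-validation noise), at `max_iter = 100`, or when the
oscillation detector fires: an oscillation event is
||b_t - b_{t-2}||_inf < tol while ||b_t - b_{t-1}||_inf >= tol (period-2
return), and three events stop the loop, returning the visited iterate
with the best penalized observed-data objective (negative Tobit
log-likelihood plus lambda*||beta||_1 on the standardized scale — a
deterministic tie-break).  The non-parametric loop uses the same
machinery with the penalized imputed-data sum of squares as its
tie-break.  A one-step variant performs exactly one imputation/refit pass
(bit-identical to the first iterate of the full loop).  With no censored
rows both loops reduce exactly to a single plain Lasso fit.
Initialization is the LOD-substitution Lasso fit, with sigma^2 from its
uncensored residuals.

## Tuning

Stratified K-fold cross-validation (censored and uncensored indices dealt
round-robin after independent seeded shuffles, continuing the deal across
groups, so per-fold censored counts differ by at most one and sizes by at
most two).  The lambda grid is log-spaced from lambda_max =
2 max_j |x_j'(y - ybar)| down to a fixed ratio (defaults: 100 points,
ratio 0.001; the experiment runners use 50 points as their problem
scale).  Within a fold the grid is traversed from largest to smallest
penalty with warm starts; the iterative methods run their full loop at
every grid value.  Ties in the CV minimum resolve toward the larger
penalty.  Two hold-out losses:

* **imputed squared error:** censored test responses are replaced by the
  learning-fold model's conditional expectation (truncated-Gaussian or
  learning-fold KM at the test row's flipped threshold; LOD or LOD/2 for
  the substitution baselines), then a mean squared error is taken;
* **Gaussian loss:** (1/n_unc) sum_unc (z_i - mu_i)^2 +
  (2 sigma^2 / n_unc) sum_cens [-ln Phi((LOD_i - mu_i)/sigma)], with
  sigma^2 from the learning-fold fit (refreshed per lambda, since each
  fit carries one); proportional to the negative Tobit log-likelihood but
  on the squared-error scale, and exactly equal to the squared loss on
  folds without censoring.  For methods that do not estimate sigma^2
  (substitution baselines, non-parametric BJ) the uncensored-residual
  variance of the learning fit is substituted and the combination is
  logged as non-canonical.  Folds without an uncensored row trigger a
  reseeded re-draw (at most 10 attempts).

K defaults to 5 for simulation work; 20 is recommended for sparse binary
predictors on real data, so infrequent mutations appear in most learning
folds.

## Low-dimensional baselines

For small p, unpenalized references: the Tobit maximum-likelihood
estimator (BFGS on (beta, log sigma) with the analytic score; uncensored
rows contribute densities, censored rows tail probabilities), median
regression on LOD-imputed data (statsmodels `QuantReg`), and Powell's
censored LAD via iterative trimming (keep rows with fitted value above
their LOD, refit LAD, stop when the kept set repeats; on a cycle the
best-objective iterate is returned).  At p = 1 and lambda = 0 the
Gaussian Buckley-James with the EM update solves the same score equations
as the Tobit MLE, and the two slopes agree to stopping tolerance — a
cross-check wired into the test suite.  These baselines are deliberately
not penalized: penalizing the non-differentiable Tobit likelihood or the
censored LAD objective is a different (and computationally hard) problem,
out of scope here.

## Synthetic data

The high-dimensional generator emulates a treatment-switch viral-load
study: Y = b0 + 0.5*Y0 + X beta + eps with baseline viral load
Y0 ~ N(12, 1) (log10 copies/mL), p = 100 binary mutation indicators at
prevalence 0.15, ten true effects of size 1, noise fixed by a 3:1
signal-to-noise ratio, and the Tobit rule applied at LOD = 1 on the
simulated scale.  Choices where the design was genuinely open:

* A multivariate Bernoulli with covariance 0.4^|i-j| does not exist for
  these margins; a Gaussian copula is used (latent stationary AR(1) with
  correlation rho^|i-j|, thresholded at the (1-prevalence) quantile).
  The induced binary-scale correlation is smaller than the latent one.
* SNR is defined as Var(linear predictor, baseline term included)/sigma^2.
* Only the intercept b0 is calibrated to the censoring target (by
  bracketed root-finding on a dedicated 1e5-row calibration sample,
  matching P(Y <= LOD) to within root-finder precision); the baseline
  slope stays at 0.5.  Only the censoring probability is identified, not
  the (LOD, b0) pair, so the LOD is pinned at 1.
* Test sets are redrawn until their censoring rate is within 0.05 of the
  training rate (the least-discrepant draw is kept after 50 tries).

The p = 1 generator (X ~ N(0,1), slope 10, SNR 4:3 so sigma^2 = 75, LOD
at the empirical quantile of the latent outcome) supports the classical
single-predictor illustration.

What the generator does **not** emulate: real mutation matrices have
block structure from resistance pathways rather than banded AR
correlation; real viral-load noise is heavier-tailed than Gaussian and
mildly heteroscedastic; assays differ across centres in more than their
LOD.  Passing benchmarks on this generator therefore demonstrate correct
behaviour under the Gaussian homoscedastic design, not robustness to
those violations (the non-parametric variant exists precisely for when
the Gaussian assumption is doubtful).

## Benchmark runners and problem sizes

`run_mse_experiment` draws paired train/test sets (default n = n_test =
100, p = 100) at censoring rates {0, 0.2, 0.5, 0.7}, tunes each method by
stratified 5-fold CV, refits at the selected penalty, and scores the mean
squared error against the latent uncensored test response.  References:
OLS on the true support with latent responses (oracle) and the Lasso on
latent responses (gold standard).  The default of 50 replicates and a
50-point grid is the package's working scale; the original design used
200 replicates (pass `reps=200` or `--full`).  The fully-iterated
Gaussian BJ pairs with the Gaussian CV loss by default, the one-step and
non-parametric variants with the imputed squared loss; overrides are a
parameter.  `run_oscillation_experiment` reports, per censoring level,
the fraction of replicates whose fully-iterated Gaussian BJ fit (at the
CV-selected penalty) terminated via oscillation detection, with binomial
standard errors and the converged/iteration-cap counts alongside.  All
replicate streams derive from a single seed through `SeedSequence`
spawning, so every table is bit-reproducible given (seed, reps, config).

## Numerical notes and limitations

* Coordinate-descent tolerance is 1e-9 (duality-gap scale) for one-off
  fits and 1e-7 inside warm-started loops; BJ stopping tolerances are two
  or more orders looser, so solver noise does not masquerade as
  non-convergence.
* Zero-variance predictor columns (e.g. a mutation absent from a CV
  learning fold) are dropped with a warning and given zero coefficients.
* sigma^2 is floored at 1e-10; reaching the floor raises rather than
  silently continuing.
* `lambda = 0` with n > p falls back to least squares; with p >= n the
  unpenalized problem is ill-posed and the grid's lower endpoint
  (0.001*lambda_max) is the practical limit.
* Standard errors for coefficients are not provided; the estimators here
  target prediction and selection, not inference.
* Heterogeneous per-row LODs are fully supported in both imputation
  engines, but with the KM variant the flipped thresholds then differ by
  row while the residual distribution is pooled — defensible under the
  homoscedastic model, and flagged here because centre-specific assays
  may violate it.
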