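# Methods

## Model and variational approximation

`mrmash` fits the matrix-variate regression Y = 1 b0' + X B + E with
E ~ MN(0, I_n, V): residuals are independent across samples and share an
r × r covariance V across conditions. Each effect vector b_j (row j of B)
has the mixture prior sum_k w0k N_r(0, S0k). The prior covariances S0k are
fixed in advance; the weights w0 and the residual covariance V are treated
as parameters and estimated by maximising the evidence lower bound (ELBO) —
empirical Bayes through variational inference.

The variational family factorises over predictors, q(B) = prod_j q_j(b_j),
and, when outcomes are partially observed, additionally over the missing
entries, q(B, Y_miss) = q(B) q(Y_miss). Under this family each q_j is
itself a mixture of multivariate normals, described by responsibilities
w1_jk, component means mu1_jk and component covariances S1_jk.

### The single-predictor kernel

Optimising q_j with everything else fixed is an exact Bayesian multivariate
simple regression. With expected residuals R_j (the data minus the fitted
contribution of every other predictor), sufficient statistics are
bhat_j = R_j' x_j / (x_j'x_j) and S_j = V / (x_j'x_j), and per component

    S1_k = S0_k (S0_k + S_j)^{-1} S_j,
    mu1_k = S1_k S_j^{-1} bhat_j,
    w1_k  ∝ w0_k N(bhat_j; 0, S0_k + S_j).

The multiplication form of S1 never inverts S0, so singular components —
including the all-zeros null and rank-1 sharing patterns — are handled
exactly. Responsibilities are normalised in log space (max-subtraction);
every solve is followed by symmetrisation (A + A')/2 so positive
semidefiniteness survives floating-point drift.

### ELBO

The ELBO is assembled from three pieces:

* the expected complete-data log-likelihood, whose quadratic term uses the
  expected residual sum of squares
  ERSS = R̄'R̄ + sum_j (x_j'x_j) Var_q(b_j) + sum_i Sigma_i, where R̄ are
  the residuals at the posterior means and Sigma_i the per-sample
  imputation covariances;
* the per-predictor Kullback–Leibler terms, computed through the
  normalising-constant identity
  −KL(q_j || prior) = log Z_j − E_{q_j}[log N(bhat_j; b_j, S_j)], with
  Z_j = sum_k w0k N(bhat_j; 0, S0k + S_j). This identity is exact for the
  (bhat_j, S_j) that produced q_j, is valid for singular components, and
  depends on neither the current residuals nor V, so the credits accumulated
  during the sweep remain exact when later blocks update;
* the Gaussian entropy of q(Y_miss).

Correctness checks built into the test suite: with p = 1 the factorised
family contains the true posterior and the converged ELBO equals the exact
log marginal likelihood (enumeration + closed-form Gaussian marginals) to
1e-8; with p = 2 it is a strict lower bound; every trajectory in the suite
is nondecreasing to 1e-6 slack, and the fitter raises if a decrease beyond
that slack ever occurs.

### Update schedule and convergence

One outer iteration performs: impute → coordinate sweep in ascending j →
intercept → w0 → V → ELBO. Each block maximises the ELBO with the others
fixed (the conditional-normal imputation is the exact optimal q(Y_miss)
because B enters the likelihood linearly), so any ordering is
ascent-preserving; this one is frozen and verified by the monotonicity
tests. Per-iteration cost is linear in n and p; the per-component
factorisations of S0k + V/(x'x) are cached per distinct value of x'x, so
with standardized predictors one set of factorisations serves the whole
sweep.

The loop stops when the ELBO improves by less than `elbo_tol` (default
0.01) **or** the posterior-mean coefficients move by less than `coef_tol`
(default 1e-6) in max-abs norm, whichever happens first; the coefficient
guard exists for edge cases (e.g. orthonormal designs that converge in one
sweep) where the ELBO criterion alone would run a redundant iteration. The
default iteration cap is 5000. Components whose estimated weight falls
below `w0_threshold` (default 1e-8) are frozen at zero at the start of the
next iteration — not mid-iteration, so the ELBO bookkeeping of the current
iteration stays exact — and retained in the output for label stability.

Initialisation: coefficients at zero unless a warm start is supplied,
weights as given by the prior template (uniform from the builders), V from
the residuals of the initial coefficients (missing entries filled with
observed column means). The fit is deterministic given its inputs.

### Intercept and scaling

Predictors are centred and, by default, scaled to unit sample variance;
the constants are stored in the fit and re-applied at prediction time, so
predictions are always on the original outcome scale. The intercept is
updated explicitly each iteration as the column means of the current
(imputed) outcomes minus the fitted genetic values. Constant predictor
columns make the simple regressions undefined; datasets flag them and the
fitter refuses them with a named error rather than emitting NaNs.

## Prior covariance collections

Canonical patterns (r × r, unscaled): identity ("independent"), all-ones
("equal effects"), one singleton e_s e_s' per condition
("condition-specific"), and unit-diagonal matrices with constant off-diagonal
0.25 / 0.5 / 0.75 ("shared with heterogeneity").

Data-driven patterns: per predictor and condition, a single-predictor
regression on the observed entries yields effect estimates and z-scores.
The strong set is the `n_strong` predictors with largest max-abs z
(default: 100 capped at p, at least 2r), further restricted to predictors
with max-abs z ≥ 3 when at least three clear that floor — ranked-but-
insignificant rows otherwise dilute the estimated sharing patterns with
sampling noise. From the strong rows E, the patterns are the uncentred
second-moment matrix E'E/n with the mean squared standard error subtracted
from its diagonal (a method-of-moments debias) and eigenvalues clipped at
zero, plus the leading `n_pcs` (default min(3, r)) rank-1 principal-axis
outer products; axes with eigenvalue below 5% of the leading one are
dropped as noise. Every pattern is normalised to unit maximum diagonal.
This is a deliberately light-weight estimator: the mash-lineage alternative
(extreme-deconvolution denoising of the patterns) is out of scope here.

Each base pattern is expanded across the scale grid
{0.01, 0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6} — prior effect variances
relative to unit outcome variance, a geometric-ish grid from sub-percent to
super-unit effects — deduplicated entrywise, and combined with the null
component (listed first) under uniform initial weights. The default recipe
is data-driven-only: in the simulation scenarios it matches or beats the
canonical and combined collections at lower cost, since its K is much
smaller.

## Synthetic data

The generator emulates multi-tissue expression prediction from genotypes.
Predictors are independent Binomial(2, MAF) dosages with per-column MAF ~
Uniform(0.05, 0.5); columns that come out constant are redrawn. There is no
linkage disequilibrium between predictors by default — real cis-windows are
strongly correlated, so passing tests here say nothing about variable
selection among correlated predictors (a documented weakness of factorised
variational families). An exchangeable residual-correlation knob
(`resid_corr`) exists for robustness checks; the default residual
covariance is diagonal.

Scenarios for the causal effect matrix (defaults: n = 600 samples of which
20% are held out, p = 200 predictors, r = 10 conditions, 5 causal
variants):

* **A — equal effects**: one draw per causal variant, copied to all
  conditions (PVE 20% everywhere).
* **B — independent effects**: independent draws per condition (PVE 20%).
* **C — mostly null**: effects in condition 1 only (PVE 20% there).
* **D — equal effects + null**: equal effects within conditions {1,2,3},
  none elsewhere.
* **E — shared effects in subgroups**: a fair coin assigns each causal
  variant to conditions {1,2,3} (PVE 20%) or to the complement (PVE 5%);
  within its subgroup the effects have constant correlation 0.8 — a
  stand-in for "shared but unequal", between equal (1.0) and independent
  (0). Assignments are redrawn until both subgroups are non-empty, since an
  empty subgroup makes its PVE target unattainable.

Effect columns are rescaled on the realised training genotypes so the
causal variants explain exactly the target proportion of variance per
condition, with residual variances set to bring every condition's total
variance to 1 — standardized RMSEs are then directly interpretable
(1 = no-signal predictor). Missingness masks training outcome entries
independently at the requested rate, redrawing any row that would lose all
entries. Everything is reproducible from (spec, seed).

## Evaluation

Standardized RMSE divides the RMSE by the standard deviation of the true
values in the test set, computed with the sample (n−1) convention — under
which the constant mean predictor scores exactly sqrt((m−1)/m) with the
population-RMSE numerator; the convention is documented because the
quotient of conventions is the only ambiguity in the definition. Relative
RMSE against a reference method is (RMSE_method − RMSE_ref)/RMSE_ref. When
accuracy is assessed over several folds, the per-fold standardized RMSEs
are averaged. The top-sharing-pattern report selects the non-null prior
component with the largest (summed across fits) weight and rescales it to a
correlation matrix; conditions with zero prior variance are flagged as
undefined rather than propagated as NaN.

## Problem sizes used in the checks

The heavier suite checks run at the generator defaults (n = 600, p = 200,
r = 10, 5 causal variants; 20 seeds for the prediction comparisons, 10 for
weight recovery and the missing-data comparison; p = 100 for the 70%-missing
comparison and p = 50 for weight recovery, where the extra predictors add
cost but no information). The prediction baseline is per-condition ridge
regression tuned by leave-one-out cross-validation over 30 penalty values.

## Known limitations

* Variational posteriors understate uncertainty; the package exposes
  posterior means for prediction and deliberately does not report credible
  intervals.
* The factorised family cannot represent posterior dependence between
  highly correlated predictors; prediction is unaffected but support
  recovery among near-duplicates is arbitrary.
* The kernel cost scales quadratically-to-cubically in r per component, so
  very large numbers of conditions call for the diagonal-V option and a
  trimmed component set.
* Data-driven patterns are estimated per dataset from marginal regressions;
  with very few strong signals they fall back gracefully (identity pattern)
  but carry little information.
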