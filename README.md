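# mrmash

Multivariate multiple regression with adaptive shrinkage priors, for
predicting several correlated outcomes — such as a gene's expression level
across many tissues — from a common set of predictors such as genetic
variant dosages. The intended users are statistical geneticists building
expression-prediction (TWAS) weights, polygenic scores or breeding values
where the outcomes share genetic effects and many outcome entries are
missing.

## Model

The data are an n × p predictor matrix **X** and an n × r outcome matrix
**Y** (possibly with missing entries), modelled as

    Y = 1 b0' + X B + E,    E ~ MN(0, I_n, V),

where **B** is the p × r effect matrix and **V** the r × r residual
covariance. Each row **b**_j of **B** (the effects of predictor j on the r
conditions) carries a mixture-of-multivariate-normals prior

    b_j | w0, S0 ~ sum_k w0k N_r(0, S0k),

whose covariance matrices S0k encode effect-sharing patterns — no effect
(the null), equal effects in every condition, condition-specific effects,
patterns learned from the data — each expanded over a grid of scales. The
mixture weights **w0** and **V** are estimated from the data by empirical
Bayes, so the prior adapts to whatever sharing structure the data support.

Fitting uses coordinate-ascent variational inference on the factorised
posterior q(B) = prod_j q_j(b_j). Each inner step solves a Bayesian
multivariate *simple* regression with the mixture prior in closed form;
outer steps update the intercept, **w0**, **V**, and — when outcomes are
missing — impute the missing entries from their conditional multivariate
normal given the observed ones. Every step increases the evidence lower
bound (ELBO), and the loop stops when the ELBO changes by less than 0.01.
Predictions for new samples are Ŷ = 1 b0' + X_new B̄, with B̄ the posterior
mean of **B**.

## Worked example

Simulate an "equal effects" dataset — 10 conditions, 200 genotype-like
predictors, 5 causal variants explaining 20% of each condition's variance —
with 70% of the training outcomes masked, then fit and evaluate:

```python
import numpy as np
from mrmash import (
    CovarianceRecipe, ScenarioSpec, build_prior, fit_mrmash, predict,
    report_top_pattern, simulate_dataset, standardized_rmse,
)

spec = ScenarioSpec(scenario="A", n=600, p=200, r=10, n_causal=5,
                    pve_high=0.2, missing_rate=0.7, seed=1)
sim = simulate_dataset(spec)

prior = build_prior(sim.train, CovarianceRecipe(kind="data_driven"))
fit = fit_mrmash(sim.train, prior)
print(f"converged: {fit.converged} after {fit.n_iter} iterations; "
      f"final ELBO {fit.elbo_trace[-1]:.1f}")
print(f"weight on the null component: {fit.prior.w0[0]:.2f}")

pat = report_top_pattern(fit)
off = pat.correlation[~np.eye(10, dtype=bool)]
print(f"top sharing pattern: {pat.label!r}, "
      f"min cross-condition correlation {off.min():.2f}")

Y_hat = predict(sim.test.X, fit)
rmse = [standardized_rmse(sim.test.Y[:, s], Y_hat[:, s]) for s in range(10)]
print("standardized RMSE per condition:", np.round(rmse, 3))
```

Output:

```
converged: True after 56 iterations; final ELBO -1923.5
weight on the null component: 0.95
top sharing pattern: 'data_driven_pc1,scale=0.1', min cross-condition correlation 1.00
standardized RMSE per condition: [0.874 0.891 1.017 0.939 0.87  0.875 0.906 0.91  0.895 0.942]
```

The fit recognises that effects are shared equally across conditions (the
dominant non-null prior pattern has cross-condition correlation 1), puts 95%
of the prior weight on the null (195 of 200 variants have no effect), and —
despite seeing only 30% of the training outcomes — predicts held-out
outcomes with standardized RMSE around 0.9, i.e. clearly better than the
no-signal baseline of 1.

The same pipeline is available from the shell:

```sh
mrmash simulate --scenario A --n 600 --p 200 --missing-rate 0.7 --seed 1 -o sim/
mrmash fit --x sim/X.tsv --y sim/Y.tsv -o model/
mrmash predict --model model/ --x sim/X_test.tsv -o pred.tsv
mrmash evaluate --truth sim/Y_test.tsv --pred mrmash=pred.tsv -o eval/
```

All matrices are TSV with header ids; `NA` marks missing outcomes. Every
command writes a manifest sufficient to replay it exactly.

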