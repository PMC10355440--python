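"""Coordinate-ascent variational empirical Bayes fitting loop.

The approximate posterior factorises over predictors, ``q(B) = prod_j q_j(b_j)``,
and — when outcomes are partially observed — over the missing entries,
``q(B, Y_miss) = q(B) q(Y_miss)``. Each outer iteration performs, in order:

1. impute missing outcome entries from the conditional multivariate normal
   given the observed entries and current (b0, B, V);
2. a coordinate sweep over predictors j = 1..p, each sweep step computing
   the single-predictor least-squares summary against the expected residuals
   and replacing q_j with the exact mixture posterior;
3. update the intercept b0;
4. empirical Bayes update of the prior mixture weights w0;
5. update of the residual covariance V from expected residual sums of squares;
6. evaluation of the evidence lower bound (ELBO).

Every step maximises the ELBO over its own block, so the ELBO trace is
nondecreasing up to floating-point slack; a decrease beyond 1e-6 raises.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from mrmash.datasets import RegressionDataset
from mrmash.model_core import (
    BmsrMixSolver,
    ConstantPredictorError,
    MixturePrior,
    NumericalError,
    PerVariablePosterior,
    _LOG_2PI,
    _symmetrize,
)

logger = logging.getLogger(__name__)


class ElboDecreaseError(RuntimeError):
    """The ELBO decreased beyond numerical slack — indicates an implementation bug."""


@dataclass(frozen=True)
class FitOptions:
    """Tunable knobs of the fitting loop.

    ``elbo_tol`` is the primary stopping rule (change in ELBO below it stops
    the loop); ``coef_tol`` is a secondary guard on the max-abs change of the
    posterior-mean coefficients. ``w0_threshold`` prunes prior components
    whose estimated weight falls below it (frozen at zero, kept in output for
    label stability). ``seed`` only feeds randomised initialisation, of which
    the default fit has none, so fits are deterministic given their inputs.
    """

    max_iter: int = 5000
    elbo_tol: float = 1e-2
    update_w0: bool = True
    update_V: bool = True
    V_structure: str = "dense"
    standardize_X: bool = True
    fit_intercept: bool = True
    w0_threshold: float = 1e-8
    coef_tol: float = 1e-6
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.elbo_tol <= 0:
            raise ValueError("elbo_tol must be positive")
        if not 0 <= self.w0_threshold <= 1e-2:
            raise ValueError("w0_threshold must lie in [0, 1e-2]")
        if self.V_structure not in ("dense", "diagonal"):
            raise ValueError("V_structure must be 'dense' or 'diagonal'")


@dataclass
class ModelFit:
    """Result of a fit: posterior means, estimated prior and residual covariance.

    ``Bbar`` is on the internal predictor scale defined by ``x_center`` and
    ``x_scale``; :func:`predict` applies the same transformation to new
    predictors, so predictions are always on the original outcome scale.
    """

    b0: np.ndarray
    Bbar: np.ndarray
    V: np.ndarray
    prior: MixturePrior
    elbo_trace: np.ndarray
    n_iter: int
    converged: bool
    Y_imputed: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    posteriors: list[PerVariablePosterior] | None = None
    predictor_ids: list[str] = field(default_factory=list)
    condition_ids: list[str] = field(default_factory=list)

    def predict(self, X_new: np.ndarray, predictor_ids: list[str] | None = None) -> np.ndarray:
        return predict(X_new, self, predictor_ids=predictor_ids)

    def save(self, directory: str | Path) -> None:
        """Serialise to a JSON manifest plus delimited matrices (round-trips exactly)."""
        from mrmash.io import write_matrix

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        p, r = self.Bbar.shape
        pids = self.predictor_ids or [f"v{j + 1:04d}" for j in range(p)]
        cids = self.condition_ids or [f"cond{s + 1:02d}" for s in range(r)]
        write_matrix(directory / "B.tsv", self.Bbar, pids, cids)
        write_matrix(directory / "V.tsv", self.V, cids, cids)
        for k in range(self.prior.K):
            write_matrix(directory / f"S0_{k:03d}.tsv", self.prior.S0[k], cids, cids)
        manifest = {
            "format": "mrmash-model-bundle",
            "b0": [float(v) for v in self.b0],
            "w0": [float(v) for v in self.prior.w0],
            "component_labels": list(self.prior.component_labels),
            "elbo_trace": [float(v) for v in self.elbo_trace],
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "x_center": [float(v) for v in self.x_center],
            "x_scale": [float(v) for v in self.x_scale],
            "predictor_ids": pids,
            "condition_ids": cids,
        }
        (directory / "model.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ModelFit":
        from mrmash.io import read_matrix

        directory = Path(directory)
        manifest = json.loads((directory / "model.json").read_text())
        Bbar, pids, cids = read_matrix(directory / "B.tsv")
        V, _, _ = read_matrix(directory / "V.tsv")
        K = len(manifest["w0"])
        S0 = np.stack(
            [read_matrix(directory / f"S0_{k:03d}.tsv")[0] for k in range(K)]
        )
        prior = MixturePrior(
            S0, np.asarray(manifest["w0"]), tuple(manifest["component_labels"])
        )
        return cls(
            b0=np.asarray(manifest["b0"], dtype=float),
            Bbar=Bbar,
            V=V,
            prior=prior,
            elbo_trace=np.asarray(manifest["elbo_trace"], dtype=float),
            n_iter=manifest["n_iter"],
            converged=manifest["converged"],
            Y_imputed=np.empty((0, len(cids))),
            x_center=np.asarray(manifest["x_center"], dtype=float),
            x_scale=np.asarray(manifest["x_scale"], dtype=float),
            predictor_ids=list(pids),
            condition_ids=list(cids),
        )


@dataclass
class FitState:
    """Snapshot of the quantities entering the ELBO at the end of an iteration."""

    n: int
    V: np.ndarray
    resid: np.ndarray
    var_sum: np.ndarray
    impute_cov_sum: np.ndarray
    impute_entropy: float
    neg_kl_sum: float


def compute_elbo(state: FitState) -> float:
    """Evidence lower bound for the current variational state.

    ``E_q[log p(Y, B | X, V, w0, S0)] - E_q[log q(B, Y_miss)]`` assembled from
    the expected residual sum of squares, the per-predictor KL credits and the
    entropy of the missing-data posterior.
    """
    n = state.n
    r = state.V.shape[0]
    try:
        cV, _ = linalg.cho_factor(state.V, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalError(f"V is not positive definite: {exc}") from exc
    logdet_V = 2.0 * float(np.log(np.diag(cV)).sum())
    erss = state.resid.T @ state.resid + state.var_sum + state.impute_cov_sum
    quad = float(np.trace(linalg.cho_solve((cV, True), erss)))
    return (
        -0.5 * n * r * _LOG_2PI
        - 0.5 * n * logdet_V
        - 0.5 * quad
        + state.impute_entropy
        + state.neg_kl_sum
    )


def _impute_rows(Y, mask, fitted, V, want_per_sample=False):
    """Conditional-normal fill of missing outcome entries, row by row.

    Returns the filled matrix, the summed conditional covariances, the summed
    Gaussian entropies, and (optionally) the per-sample covariance blocks.
    """
    n, r = Y.shape
    Y_filled = np.where(mask, Y, 0.0)
    cov_sum = np.zeros((r, r))
    entropy = 0.0
    per_sample = np.zeros((n, r, r)) if want_per_sample else None
    half_log_2pie = 0.5 * (_LOG_2PI + 1.0)
    for i in np.flatnonzero(~mask.all(axis=1)):
        obs = mask[i]
        mis = ~obs
        if not obs.any():
            # all-missing row: prior-predictive moments
            cond_mean = fitted[i, mis]
            cond_cov = V[np.ix_(mis, mis)]
        else:
            Voo = V[np.ix_(obs, obs)]
            Vmo = V[np.ix_(mis, obs)]
            try:
                cOO, _ = linalg.cho_factor(Voo, lower=True)
            except linalg.LinAlgError as exc:
                raise NumericalError(
                    f"singular observed-block covariance for sample {i}: {exc}"
                ) from exc
            gain = Vmo @ linalg.cho_solve((cOO, True), np.eye(int(obs.sum())))
            cond_mean = fitted[i, mis] + gain @ (Y[i, obs] - fitted[i, obs])
            cond_cov = _symmetrize(V[np.ix_(mis, mis)] - gain @ Vmo.T)
        Y_filled[i, mis] = cond_mean
        cov_full = np.zeros((r, r))
        cov_full[np.ix_(mis, mis)] = cond_cov
        cov_sum += cov_full
        sign, logdet = np.linalg.slogdet(cond_cov)
        if sign <= 0:
            raise NumericalError(f"non-PD conditional covariance for sample {i}")
        entropy += half_log_2pie * int(mis.sum()) + 0.5 * logdet
        if want_per_sample:
            per_sample[i] = cov_full
    return Y_filled, cov_sum, entropy, per_sample


def impute_missing(Y, mask, b0, Bbar, X, V):
    """Fill missing outcome entries with their conditional posterior means.

    The fill for sample i with missing set m and observed set o is
    ``mu_m + V_mo V_oo^{-1} (y_o - mu_o)`` where ``mu = b0 + Bbar' x_i``; the
    conditional covariance (zero block on observed coordinates) is returned
    per sample for use in covariance updates. Observed entries pass through.
    """
    Y = np.asarray(Y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    fitted = np.asarray(b0, dtype=float)[None, :] + np.asarray(X, float) @ np.asarray(
        Bbar, float
    )
    Y_filled, _, _, per_sample = _impute_rows(Y, mask, fitted, V, want_per_sample=True)
    return Y_filled, per_sample


def fit_mrmash(
    data: RegressionDataset,
    prior: MixturePrior,
    options: FitOptions | None = None,
    init: np.ndarray | None = None,
    V_init: np.ndarray | None = None,
) -> ModelFit:
    """Fit the multivariate regression by coordinate-ascent variational EB.

    Parameters
    ----------
    data
        Training data; missing outcomes (per ``data.mask``) are imputed
        inside the loop.
    prior
        Mixture prior template; its weights are re-estimated when
        ``options.update_w0`` (the default).
    options
        See :class:`FitOptions`.
    init
        Optional p x r coefficient initialisation on the original predictor
        scale (e.g. from a penalised-regression fit). Defaults to zeros.
    V_init
        Optional fixed/initial residual covariance. Defaults to the sample
        covariance of the initial residuals.
    """
    opts = options or FitOptions()
    if prior.r != data.r:
        raise ValueError(f"prior is for r={prior.r} conditions, data has r={data.r}")
    n, p, r = data.n, data.p, data.r
    X = data.X
    Y = data.Y
    mask = data.mask
    has_missing = not mask.all()

    const = data.constant_predictors
    if const.any():
        bad = [data.predictor_ids[j] for j in np.flatnonzero(const)[:10]]
        raise ConstantPredictorError(
            f"constant predictor column(s): {', '.join(bad)}"
        )
    x_center = X.mean(axis=0) if opts.fit_intercept else np.zeros(p)
    if opts.standardize_X:
        x_scale = X.std(axis=0, ddof=1)
    else:
        x_scale = np.ones(p)
    Xc = (X - x_center) / x_scale
    xtx = np.einsum("ij,ij->j", Xc, Xc)
    if (xtx <= 0).any():
        bad = [data.predictor_ids[j] for j in np.flatnonzero(xtx <= 0)[:10]]
        raise ConstantPredictorError(f"constant predictor column(s): {', '.join(bad)}")

    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape != (p, r):
            raise ValueError(f"init must have shape ({p}, {r})")
        mu = init * x_scale[:, None]
    else:
        mu = np.zeros((p, r))

    col_means = np.array(
        [Y[mask[:, s], s].mean() for s in range(r)]
    )
    Y_fill0 = np.where(mask, Y, col_means[None, :])
    b0 = (
        (Y_fill0 - Xc @ mu).mean(axis=0) if opts.fit_intercept else np.zeros(r)
    )
    if V_init is not None:
        V = _symmetrize(np.asarray(V_init, dtype=float))
    else:
        R0 = Y_fill0 - b0[None, :] - Xc @ mu
        V = _symmetrize(R0.T @ R0 / n)
        mineig = linalg.eigvalsh(V)[0]
        if mineig < 1e-8:
            V = V + (1e-8 - min(mineig, 0.0)) * np.eye(r)
    if opts.V_structure == "diagonal":
        V = np.diag(np.diag(V))

    w0 = prior.w0.copy()
    prev_elbo = -np.inf
    elbo_trace: list[float] = []
    converged = False
    w1_mat = np.zeros((p, prior.K))
    mu1_all = np.zeros((p, prior.K, r))
    solver_of: list[BmsrMixSolver] = []
    n_iter = 0

    for it in range(1, opts.max_iter + 1):
        n_iter = it
        if opts.update_w0 and opts.w0_threshold > 0:
            small = (w0 > 0) & (w0 < opts.w0_threshold)
            if small.any():
                w0 = np.where(small, 0.0, w0)
                w0 = w0 / w0.sum()
        working_prior = prior.with_weights(w0)

        fitted = b0[None, :] + Xc @ mu
        if has_missing:
            Ytilde, cov_sum, entropy, _ = _impute_rows(Y, mask, fitted, V)
        else:
            Ytilde = Y
            cov_sum = np.zeros((r, r))
            entropy = 0.0
        resid = Ytilde - fitted

        solvers: dict[float, BmsrMixSolver] = {}
        mu_before = mu.copy()
        neg_kl_sum = 0.0
        var_sum = np.zeros((r, r))
        solver_of = []
        for j in range(p):
            key = float(xtx[j])
            solver = solvers.get(key)
            if solver is None:
                solver = BmsrMixSolver(working_prior, V / key)
                solvers[key] = solver
            xj = Xc[:, j]
            bhat = xj @ resid / key + mu[j]
            w1, mu1, mean_j, smom_j, neg_kl = solver.posterior(bhat)
            resid -= np.outer(xj, mean_j - mu[j])
            mu[j] = mean_j
            w1_mat[j] = w1
            mu1_all[j] = mu1
            var_sum += key * (smom_j - np.outer(mean_j, mean_j))
            neg_kl_sum += neg_kl
            solver_of.append(solver)

        if opts.fit_intercept:
            shift = resid.mean(axis=0)
            b0 = b0 + shift
            resid = resid - shift[None, :]

        if opts.update_w0:
            w0_new = w1_mat.mean(axis=0)
            col_mass = w1_mat.sum(axis=0)
            both = (col_mass > 0) & (w0 > 0) & (w0_new > 0)
            neg_kl_sum += float(
                (col_mass[both] * (np.log(w0_new[both]) - np.log(w0[both]))).sum()
            )
            w0 = w0_new

        if opts.update_V:
            erss = resid.T @ resid + var_sum + cov_sum
            V = _symmetrize(erss / n)
            if opts.V_structure == "diagonal":
                V = np.diag(np.diag(V))

        state = FitState(
            n=n,
            V=V,
            resid=resid,
            var_sum=var_sum,
            impute_cov_sum=cov_sum,
            impute_entropy=entropy,
            neg_kl_sum=neg_kl_sum,
        )
        elbo = compute_elbo(state)
        if not np.isfinite(elbo):
            raise NumericalError(f"non-finite ELBO at iteration {it}")
        elbo_trace.append(elbo)
        if opts.verbose:
            logger.info("iteration %d: ELBO = %.6f", it, elbo)
        if it > 1:
            delta = elbo - prev_elbo
            if delta < -1e-6:
                raise ElboDecreaseError(
                    f"ELBO decreased by {-delta:g} at iteration {it} "
                    "(after the V update)"
                )
            coef_delta = float(np.abs(mu - mu_before).max())
            if delta < opts.elbo_tol or coef_delta < opts.coef_tol:
                converged = True
                break
        prev_elbo = elbo

    posteriors = [
        PerVariablePosterior(
            w1=w1_mat[j].copy(), mu1=mu1_all[j].copy(), S1=solver_of[j].S1, mean=mu[j].copy()
        )
        for j in range(p)
    ]
    if has_missing:
        fitted = b0[None, :] + Xc @ mu
        Y_imputed, _, _, _ = _impute_rows(Y, mask, fitted, V)
    else:
        Y_imputed = Y.copy()

    return ModelFit(
        b0=b0,
        Bbar=mu,
        V=V,
        prior=prior.with_weights(w0),
        elbo_trace=np.asarray(elbo_trace),
        n_iter=n_iter,
        converged=converged,
        Y_imputed=Y_imputed,
        x_center=x_center,
        x_scale=x_scale,
        posteriors=posteriors,
        predictor_ids=list(data.predictor_ids),
        condition_ids=list(data.condition_ids),
    )


def predict(
    X_new: np.ndarray, fit: ModelFit, predictor_ids: list[str] | None = None
) -> np.ndarray:
    """Predict outcomes for new samples from the posterior-mean coefficients."""
    X_new = np.asarray(X_new, dtype=float)
    p = fit.Bbar.shape[0]
    if X_new.ndim != 2 or X_new.shape[1] != p:
        raise ValueError(f"X_new must have {p} columns, got {X_new.shape}")
    if predictor_ids is not None and fit.predictor_ids:
        missing = [i for i in fit.predictor_ids if i not in set(predictor_ids)]
        extra = [i for i in predictor_ids if i not in set(fit.predictor_ids)]
        if missing or extra:
            raise ValueError(
                f"predictor id mismatch: missing {missing[:5]}, extra {extra[:5]}"
            )
        order = [predictor_ids.index(i) for i in fit.predictor_ids]
        X_new = X_new[:, order]
    Xs = (X_new - fit.x_center) / fit.x_scale
    return fit.b0[None, :] + Xs @ fit.Bbar
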