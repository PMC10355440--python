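"""Bayesian multivariate simple regression with a mixture-of-normals prior.

This is the computational kernel of the package: given the least-squares
summary (``bhat``, ``S``) of a single predictor against an r-condition
residual matrix, compute the exact posterior of its effect vector under a
mixture-of-multivariate-normals prior. The posterior is again a mixture of
multivariate normals, characterised by responsibilities ``w1``, component
means ``mu1`` and component covariances ``S1``.

All component algebra is written so that singular prior covariances —
including the all-zeros "null" component — are handled exactly, via the
identity ``S1 = S0 (S0 + S)^{-1} S`` which never inverts ``S0``. Mixture
weights are normalised in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import logsumexp

_LOG_2PI = float(np.log(2.0 * np.pi))


class ConstantPredictorError(ValueError):
    """A predictor column has zero variance, so its simple regression is undefined."""


class NumericalError(RuntimeError):
    """A numerical operation (factorisation, normalisation) failed irrecoverably."""


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + np.swapaxes(a, -1, -2))


@dataclass(frozen=True)
class MixturePrior:
    """Mixture-of-multivariate-normals prior on an r-vector of effects.

    Parameters
    ----------
    S0
        Array of shape (K, r, r): symmetric PSD prior covariance matrices.
        If a null (all-zeros) component is present it must be listed first.
    w0
        Length-K mixture weights on the simplex.
    component_labels
        Human-readable label per component.
    """

    S0: np.ndarray
    w0: np.ndarray
    component_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        S0 = np.ascontiguousarray(np.asarray(self.S0, dtype=float))
        w0 = np.asarray(self.w0, dtype=float)
        if S0.ndim != 3 or S0.shape[1] != S0.shape[2]:
            raise ValueError("S0 must have shape (K, r, r)")
        K = S0.shape[0]
        if w0.shape != (K,):
            raise ValueError(f"w0 must have length {K}")
        if (w0 < 0).any():
            raise ValueError("mixture weights must be non-negative")
        if abs(w0.sum() - 1.0) > 1e-12:
            raise ValueError(f"mixture weights must sum to 1, got {w0.sum()!r}")
        asym = np.abs(S0 - np.swapaxes(S0, 1, 2)).max() if K else 0.0
        if asym > 1e-12:
            raise ValueError(f"prior covariances must be symmetric (max deviation {asym:g})")
        for k in range(K):
            mineig = linalg.eigvalsh(S0[k])[0] if S0.shape[1] else 0.0
            if mineig < -1e-10:
                raise ValueError(
                    f"prior covariance {k} is not positive semidefinite "
                    f"(smallest eigenvalue {mineig:g})"
                )
        is_null = ~S0.any(axis=(1, 2))
        if is_null.any() and not is_null[0]:
            raise ValueError("a null (all-zeros) component must be listed first")
        labels = tuple(self.component_labels)
        if labels and len(labels) != K:
            raise ValueError("component_labels length must equal K")
        if not labels:
            labels = tuple(f"component_{k}" for k in range(K))
        object.__setattr__(self, "S0", S0)
        object.__setattr__(self, "w0", w0)
        object.__setattr__(self, "component_labels", labels)

    @property
    def K(self) -> int:
        return self.S0.shape[0]

    @property
    def r(self) -> int:
        return self.S0.shape[1]

    @property
    def null_index(self) -> int | None:
        """Index of the null component, or None if absent."""
        return 0 if self.K and not self.S0[0].any() else None

    def with_weights(self, w0: np.ndarray) -> "MixturePrior":
        """Same covariances and labels, new weights."""
        return MixturePrior(self.S0, w0, self.component_labels)


@dataclass
class PerVariablePosterior:
    """Mixture posterior of one predictor's effect vector.

    ``mean`` and ``second_moment`` are the responsibility-blended first and
    second posterior moments, the quantities the fitting loop consumes.
    """

    w1: np.ndarray
    mu1: np.ndarray
    S1: np.ndarray
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    second_moment: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.mu1 = np.asarray(self.mu1, dtype=float)
        self.S1 = np.asarray(self.S1, dtype=float)
        if self.mean is None:
            self.mean = self.w1 @ self.mu1
        if self.second_moment is None:
            self.second_moment = np.einsum("k,kij->ij", self.w1, self.S1) + np.einsum(
                "k,ki,kj->ij", self.w1, self.mu1, self.mu1
            )


def univariate_stats(x: np.ndarray, R: np.ndarray, V: np.ndarray):
    """Least-squares summary of one predictor against an expected-residual matrix.

    Returns ``bhat = R'x / (x'x)`` and its sampling covariance ``S = V / (x'x)``
    under residual covariance ``V``.
    """
    x = np.asarray(x, dtype=float)
    R = np.asarray(R, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.ptp(x) == 0:
        raise ConstantPredictorError("constant predictor: x has zero variance")
    xtx = float(x @ x)
    if xtx <= 0:
        raise ConstantPredictorError("constant predictor: x'x is not positive")
    bhat = R.T @ x / xtx
    S = V / xtx
    return bhat, S


class BmsrMixSolver:
    """Precomputed factorisations for repeated posterior evaluation.

    The per-component matrices ``C_k = S0_k + S`` depend only on the prior and
    on ``S``; inside the fitting loop ``S = V / (x'x)`` is shared by every
    predictor with the same sum of squares, so one solver serves them all.
    """

    def __init__(self, prior: MixturePrior, S: np.ndarray):
        S = _symmetrize(np.asarray(S, dtype=float))
        r = prior.r
        if S.shape != (r, r):
            raise ValueError(f"S must be {r}x{r}")
        try:
            cS, _ = linalg.cho_factor(S, lower=True)
        except linalg.LinAlgError as exc:
            raise NumericalError(f"S is not positive definite: {exc}") from exc
        self.prior = prior
        self.S = S
        self.Sinv = linalg.cho_solve((cS, True), np.eye(r))
        self.logdet_S = 2.0 * float(np.log(np.diag(cS)).sum())
        K = prior.K
        C = _symmetrize(prior.S0 + S[None, :, :])
        self.Cinv = np.empty_like(C)
        self.logdet_C = np.empty(K)
        for k in range(K):
            try:
                cC, _ = linalg.cho_factor(C[k], lower=True)
            except linalg.LinAlgError as exc:
                raise NumericalError(
                    f"component {k} ({prior.component_labels[k]}): "
                    f"S0 + S is not positive definite: {exc}"
                ) from exc
            self.Cinv[k] = linalg.cho_solve((cC, True), np.eye(r))
            self.logdet_C[k] = 2.0 * float(np.log(np.diag(cC)).sum())
        # A_k maps bhat to the component posterior mean; S1_k = A_k S.
        self.A = prior.S0 @ self.Cinv
        self.S1 = _symmetrize(self.A @ S)
        with np.errstate(divide="ignore"):
            self.logw0 = np.log(prior.w0)
        self._r = r

    def posterior(self, bhat: np.ndarray):
        """Responsibilities, blended moments and the per-variable KL credit.

        Returns ``(w1, mu1, mean, second_moment, neg_kl)`` where ``neg_kl`` is
        ``-KL(q || prior)`` computed from the normalising constant identity
        ``log Z - E_q[log N(bhat; b, S)]``; it feeds the evidence lower bound.
        """
        bhat = np.asarray(bhat, dtype=float)
        r = self._r
        quad = np.einsum("kij,i,j->k", self.Cinv, bhat, bhat)
        loglik = -0.5 * (r * _LOG_2PI + self.logdet_C + quad)
        logw = self.logw0 + loglik
        log_z = float(logsumexp(logw))
        if not np.isfinite(log_z):
            raise NumericalError(
                f"all component log-weights are non-finite for bhat={bhat!r}"
            )
        w1 = np.exp(logw - log_z)
        mu1 = self.A @ bhat
        mean = w1 @ mu1
        second_moment = np.einsum("k,kij->ij", w1, self.S1) + np.einsum(
            "k,ki,kj->ij", w1, mu1, mu1
        )
        var = second_moment - np.outer(mean, mean)
        dev = bhat - mean
        e_loglik = -0.5 * (
            r * _LOG_2PI
            + self.logdet_S
            + dev @ self.Sinv @ dev
            + float(np.trace(self.Sinv @ var))
        )
        neg_kl = log_z - e_loglik
        return w1, mu1, mean, second_moment, neg_kl


def bmsr_mix_posterior(
    bhat: np.ndarray, S: np.ndarray, prior: MixturePrior
) -> PerVariablePosterior:
    """Exact posterior of a single effect vector under the mixture prior.

    For each component k the posterior is normal with covariance
    ``S1_k = S0_k (S0_k + S)^{-1} S`` and mean ``S1_k S^{-1} bhat``, and the
    responsibilities are ``w1_k propto w0_k N(bhat; 0, S0_k + S)``.
    """
    solver = BmsrMixSolver(prior, S)
    w1, mu1, mean, second_moment, _ = solver.posterior(np.asarray(bhat, dtype=float))
    return PerVariablePosterior(
        w1=w1, mu1=mu1, S1=solver.S1.copy(), mean=mean, second_moment=second_moment
    )
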