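"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's closed-form component algebra: mixture
posteriors are computed by dense numerical quadrature (per component, on the
support of the prior component), and exact log marginal likelihoods by
enumeration of component assignments with closed-form Gaussian marginals.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate
from scipy.special import logsumexp
from scipy.stats import multivariate_normal, norm


def _gauss_logpdf(x, mean, cov):
    return multivariate_normal.logpdf(x, mean=mean, cov=cov)


def component_posterior_quadrature(bhat, S, S0, npts=801):
    """Moments of one mixture component's posterior by quadrature.

    The component prior N(0, S0) may be singular; quadrature runs on its
    support (eigenvectors with positive eigenvalues). Returns
    (log_marginal, mean, second_moment).
    """
    bhat = np.asarray(bhat, dtype=float)
    S = np.atleast_2d(np.asarray(S, dtype=float))
    S0 = np.atleast_2d(np.asarray(S0, dtype=float))
    r = len(bhat)
    eigval, eigvec = np.linalg.eigh(S0)
    keep = eigval > 1e-12 * max(eigval.max(), 1.0)
    d = int(keep.sum())
    if d == 0:
        # point mass at zero
        return _gauss_logpdf(bhat, np.zeros(r), S), np.zeros(r), np.zeros((r, r))
    U = eigvec[:, keep]
    lam = eigval[keep]
    if d == 1:
        u = U[:, 0]
        sd_prior = np.sqrt(lam[0])

        def integrand(t, power):
            b = t * u
            ll = _gauss_logpdf(bhat, b, S) + norm.logpdf(t, 0.0, sd_prior)
            return np.exp(ll) * t**power

        lim = 12 * sd_prior + abs(bhat @ u) + 12 * np.sqrt(np.diag(S).max())
        z, _ = integrate.quad(integrand, -lim, lim, args=(0,), limit=200)
        m1, _ = integrate.quad(integrand, -lim, lim, args=(1,), limit=200)
        m2, _ = integrate.quad(integrand, -lim, lim, args=(2,), limit=200)
        mean = (m1 / z) * u
        smom = (m2 / z) * np.outer(u, u)
        return np.log(z), mean, smom
    if d == 2 and r == 2:
        lim = float(np.abs(bhat).max() + 10 * np.sqrt(np.diag(S).max() + eigval.max()))
        grid = np.linspace(-lim, lim, npts)
        B1, B2 = np.meshgrid(grid, grid, indexing="ij")
        pts = np.stack([B1.ravel(), B2.ravel()], axis=1)
        logf = _gauss_logpdf(pts, bhat, S) + _gauss_logpdf(pts, np.zeros(2), S0)
        f = np.exp(logf).reshape(npts, npts)
        z = np.trapezoid(np.trapezoid(f, grid, axis=1), grid)
        mean = np.array(
            [
                np.trapezoid(np.trapezoid(f * B1, grid, axis=1), grid),
                np.trapezoid(np.trapezoid(f * B2, grid, axis=1), grid),
            ]
        ) / z
        smom = np.empty((2, 2))
        for a, Ba in enumerate((B1, B2)):
            for b, Bb in enumerate((B1, B2)):
                smom[a, b] = np.trapezoid(
                    np.trapezoid(f * Ba * Bb, grid, axis=1), grid
                ) / z
        return np.log(z), mean, smom
    raise NotImplementedError("oracle supports r <= 2 only")


def mixture_posterior_quadrature(bhat, S, S0_list, w0):
    """Full mixture posterior (responsibilities + blended moments) by quadrature."""
    logz = np.empty(len(w0))
    means = []
    smoms = []
    for k, S0 in enumerate(S0_list):
        lz, m, sm = component_posterior_quadrature(bhat, S, S0)
        logz[k] = lz
        means.append(m)
        smoms.append(sm)
    logw = np.log(np.asarray(w0)) + logz
    w1 = np.exp(logw - logsumexp(logw))
    mean = sum(w * m for w, m in zip(w1, means))
    smom = sum(w * sm for w, sm in zip(w1, smoms))
    return w1, mean, smom


def exact_log_marginal(X, y, w0, s0_scalars, tau2):
    """Exact log marginal likelihood of a univariate-outcome model (r = 1).

    Enumerates the K^p component assignments; each term is a closed-form
    Gaussian marginal N(y; 0, sum_j s0_{k_j} x_j x_j' + tau2 I).
    """
    n, p = X.shape
    terms = []
    logw0 = np.log(np.asarray(w0, dtype=float))
    for combo in itertools.product(range(len(w0)), repeat=p):
        cov = tau2 * np.eye(n)
        for j, k in enumerate(combo):
            cov += s0_scalars[k] * np.outer(X[:, j], X[:, j])
        terms.append(
            sum(logw0[k] for k in combo)
            + multivariate_normal.logpdf(y, np.zeros(n), cov)
        )
    return float(logsumexp(terms))


def per_column_ols(x, R):
    """Per-column one-predictor least squares (no intercept), the plain way."""
    return np.array([np.linalg.lstsq(x[:, None], R[:, s], rcond=None)[0][0]
                     for s in range(R.shape[1])])
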