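"""Cumulative-logit (proportional-odds) regression.

The model for an ordered outcome Y in {1..K} with covariates x is

    P(Y <= k | x) = logistic(theta_k - x'beta),   theta_1 < ... < theta_{K-1},

so a positive coefficient raises the odds of a *worse* (higher) category at
every threshold.  The likelihood is exposed as a pure function
(:func:`proportional_odds_loglik`) so that brute-force oracles and the fitter
share one definition.  The fitter supports case weights (sufficient-statistic
aggregation), record-level offsets and an optional ridge penalty on the
regression coefficients, used as a fallback under monotone likelihood.

Standard errors come from the observed information (numerically differentiated
analytic gradient) in the natural (thresholds, beta) parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logit

__all__ = ["proportional_odds_loglik", "fit_proportional_odds", "ProportionalOddsFit"]


def _check_levels(levels: np.ndarray, n_levels: int) -> None:
    if levels.min() < 1 or levels.max() > n_levels:
        raise ValueError("levels must lie in 1..n_levels")


def proportional_odds_loglik(
    thresholds,
    beta,
    X,
    levels,
    weights=None,
    offset=None,
) -> float:
    """Exact cumulative-logit log-likelihood (pure function of its inputs)."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    levels = np.asarray(levels, dtype=int)
    K = thresholds.size + 1
    _check_levels(levels, K)
    ll, _, _ = _loglik_parts(thresholds, beta, X, levels, weights, offset)
    return float(ll)


def _loglik_parts(thresholds, beta, X, levels, weights, offset):
    """Return (loglik, dll/dtheta, dll/deta_per_obs_summed_into_beta_space)."""
    n = len(levels)
    K = thresholds.size + 1
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    eta = X @ beta if beta.size else np.zeros(n)
    if offset is not None:
        eta = eta + np.asarray(offset, dtype=float)

    upper_idx = levels - 1          # theta index for upper bound; == K-1 -> +inf
    lower_idx = levels - 2          # theta index for lower bound; == -1  -> -inf
    has_upper = levels < K
    has_lower = levels > 1

    u = np.where(has_upper, thresholds[np.minimum(upper_idx, K - 2)] - eta, np.inf)
    l = np.where(has_lower, thresholds[np.maximum(lower_idx, 0)] - eta, -np.inf)

    # log(P) = log sigma(u) + log sigma(-l) + log(1 - exp(l - u)), stable form
    logp = np.zeros(n)
    both = has_upper & has_lower
    only_u = has_upper & ~has_lower
    only_l = ~has_upper & has_lower
    logp[only_u] = log_expit(u[only_u])
    logp[only_l] = log_expit(-l[only_l])
    if both.any():
        d = l[both] - u[both]  # < 0
        logp[both] = (
            log_expit(u[both]) + log_expit(-l[both]) + np.log(-np.expm1(d))
        )
    ll = float(np.dot(w, logp))

    # gradient pieces
    gu = np.where(has_upper, expit(u), 1.0)
    gl = np.where(has_lower, expit(l), 0.0)
    P = np.maximum(gu - gl, 1e-300)
    fu = np.where(has_upper, gu * (1.0 - gu), 0.0)
    fl = np.where(has_lower, gl * (1.0 - gl), 0.0)

    dll_deta = w * (fl - fu) / P
    dll_dtheta = np.zeros(K - 1)
    if has_upper.any():
        np.add.at(dll_dtheta, upper_idx[has_upper], (w * fu / P)[has_upper])
    if has_lower.any():
        np.subtract.at(dll_dtheta, lower_idx[has_lower], (w * fl / P)[has_lower])
    return ll, dll_dtheta, dll_deta


@dataclass
class ProportionalOddsFit:
    thresholds: np.ndarray
    beta: np.ndarray
    cov: Optional[np.ndarray]   # observed-information covariance, natural params
    llf: float
    converged: bool
    penalized: bool
    n_obs: float
    n_iter: int

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.thresholds, self.beta])

    def beta_cov(self) -> Optional[np.ndarray]:
        if self.cov is None:
            return None
        k = self.thresholds.size
        return self.cov[k:, k:]

    def beta_se(self) -> Optional[np.ndarray]:
        cov = self.beta_cov()
        return None if cov is None else np.sqrt(np.diag(cov))


def _nll_grad_natural(params, X, levels, weights, offset, K, ridge):
    thetas = params[: K - 1]
    beta = params[K - 1:]
    ll, dth, deta = _loglik_parts(thetas, beta, X, levels, weights, offset)
    gbeta = X.T @ deta if beta.size else np.zeros(0)
    nll = -ll
    grad = -np.concatenate([dth, gbeta])
    if ridge > 0 and beta.size:
        nll += 0.5 * ridge * float(beta @ beta)
        grad[K - 1:] += ridge * beta
    return nll, grad


def _to_natural(z, K):
    thetas = np.empty(K - 1)
    thetas[0] = z[0]
    if K > 2:
        thetas[1:] = z[0] + np.cumsum(np.exp(z[1: K - 1]))
    return np.concatenate([thetas, z[K - 1:]])


def fit_proportional_odds(
    X: np.ndarray,
    levels: np.ndarray,
    n_levels: Optional[int] = None,
    weights: Optional[np.ndarray] = None,
    offset: Optional[np.ndarray] = None,
    ridge: float = 0.0,
    compute_cov: bool = True,
    start: Optional[np.ndarray] = None,
    maxiter: int = 1000,
) -> ProportionalOddsFit:
    """Maximum-likelihood proportional-odds fit.

    Thresholds are optimized through an increasing reparameterization
    (theta_1, log-increments); standard errors are reported in the natural
    parameterization.  ``ridge`` adds an L2 penalty on ``beta`` only.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    levels = np.asarray(levels, dtype=int)
    if X.shape[0] != levels.size:
        raise ValueError("X and levels have incompatible shapes")
    K = int(n_levels) if n_levels is not None else int(levels.max())
    if K < 2:
        raise ValueError("need at least 2 outcome levels")
    observed = np.unique(levels)
    if observed.size < 2:
        raise ValueError("need at least 2 distinct observed levels")
    _check_levels(levels, K)
    p = X.shape[1]
    w = np.ones(levels.size) if weights is None else np.asarray(weights, dtype=float)

    if start is None:
        # marginal cumulative logits as threshold starts
        freq = np.bincount(levels, weights=w, minlength=K + 1)[1:]
        cum = np.cumsum(freq) / freq.sum()
        cum = np.clip(cum[:-1], 1e-4, 1 - 1e-4)
        theta0 = logit(cum)
        theta0 = np.maximum.accumulate(theta0)
        # enforce strict increase
        for i in range(1, theta0.size):
            if theta0[i] <= theta0[i - 1]:
                theta0[i] = theta0[i - 1] + 1e-3
        start = np.concatenate([theta0, np.zeros(p)])

    z0 = np.empty(K - 1 + p)
    z0[0] = start[0]
    if K > 2:
        z0[1: K - 1] = np.log(np.maximum(np.diff(start[: K - 1]), 1e-6))
    z0[K - 1:] = start[K - 1:]

    def fun(z):
        params = _to_natural(z, K)
        nll, grad = _nll_grad_natural(params, X, levels, w, offset, K, ridge)
        # chain rule back to z
        gz = np.empty_like(z)
        dth = grad[: K - 1]
        gz[0] = dth.sum()
        if K > 2:
            # dtheta_j/dz_k = exp(z_k) for j >= k (k = 1..K-2)
            rev_cumsum = np.cumsum(dth[::-1])[::-1]
            gz[1: K - 1] = np.exp(z[1: K - 1]) * rev_cumsum[1:]
        gz[K - 1:] = grad[K - 1:]
        return nll, gz

    res = minimize(fun, z0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
    params = _to_natural(res.x, K)
    thetas = params[: K - 1]
    beta = params[K - 1:]
    nll, grad = _nll_grad_natural(params, X, levels, w, offset, K, ridge)

    cov = None
    if compute_cov:
        cov = _observed_information_cov(params, X, levels, w, offset, K, ridge)
    converged = bool(res.success) or float(np.max(np.abs(grad))) < 1e-4 * max(
        1.0, w.sum() / 100.0
    )
    return ProportionalOddsFit(
        thresholds=thetas,
        beta=beta,
        cov=cov,
        llf=-float(nll) + (0.5 * ridge * float(beta @ beta) if ridge > 0 else 0.0),
        converged=converged,
        penalized=ridge > 0,
        n_obs=float(w.sum()),
        n_iter=int(res.nit),
    )


def _observed_information_cov(params, X, levels, w, offset, K, ridge,
                              eps: float = 1e-5):
    """Covariance from central finite differences of the analytic gradient."""
    m = params.size
    H = np.empty((m, m))
    for j in range(m):
        step = eps * max(1.0, abs(params[j]))
        hi = params.copy(); hi[j] += step
        lo = params.copy(); lo[j] -= step
        _, ghi = _nll_grad_natural(hi, X, levels, w, offset, K, ridge)
        _, glo = _nll_grad_natural(lo, X, levels, w, offset, K, ridge)
        H[:, j] = (ghi - glo) / (2.0 * step)
    H = 0.5 * (H + H.T)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)
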