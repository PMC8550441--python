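"""Model fitting primitives shared by the CI tests and equivalence tests.

Linear-Gaussian models are fit by least squares with the maximum-likelihood
residual variance. Logistic models are fit by Newton-IRLS with a small ridge
retry on non-convergence; separation is expected on small samples, so a
capped, flagged result is always returned rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Probabilities are clipped before logs so per-sample log-likelihoods stay
# finite even under (quasi-)separation.
_PROB_EPS = 1e-12
_IRLS_TOL = 1e-8
_IRLS_MAX_ITER = 100
_IRLS_RIDGE = 1e-6
_DESIGN_JITTER = 1e-8


@dataclass
class GaussianFit:
    coef: np.ndarray  # intercept first
    sigma2: float  # MLE residual variance
    loglik: float
    flagged: bool = False

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return _design(Z) @ self.coef


@dataclass
class LogisticFit:
    coef: np.ndarray  # intercept first
    loglik: float
    converged: bool
    flagged: bool = False

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def predict(self, Z: np.ndarray) -> np.ndarray:
        eta = _design(Z) @ self.coef
        return _sigmoid(eta)


def _design(Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n = Z.shape[0]
    return np.hstack([np.ones((n, 1)), Z])


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fit_gaussian(Z: np.ndarray, y: np.ndarray) -> GaussianFit:
    """Ordinary least squares with Gaussian MLE variance.

    A singular design gets a tiny ridge jitter and the fit is flagged.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if Z is None or np.size(Z) == 0:
        Z = np.empty((n, 0))
    D = _design(Z)
    flagged = False
    gram = D.T @ D
    try:
        cond = np.linalg.cond(gram)
    except np.linalg.LinAlgError:  # pragma: no cover - cond rarely fails
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        gram = gram + _DESIGN_JITTER * np.eye(gram.shape[0])
        flagged = True
    coef = np.linalg.solve(gram, D.T @ y)
    resid = y - D @ coef
    sigma2 = float(np.mean(resid**2))
    sigma2 = max(sigma2, _PROB_EPS)
    loglik = float(np.sum(gaussian_loglik_vector(y, D @ coef, sigma2)))
    return GaussianFit(coef=coef, sigma2=sigma2, loglik=loglik, flagged=flagged)


def gaussian_loglik_vector(y, mu, sigma2) -> np.ndarray:
    resid = np.asarray(y, dtype=float) - np.asarray(mu, dtype=float)
    return -0.5 * (np.log(2.0 * np.pi * sigma2) + resid**2 / sigma2)


def bernoulli_loglik_vector(y, p) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), _PROB_EPS, 1.0 - _PROB_EPS)
    y = np.asarray(y, dtype=float)
    return y * np.log(p) + (1.0 - y) * np.log1p(-p)


def _irls(D: np.ndarray, y: np.ndarray, ridge: float) -> tuple:
    """One Newton-IRLS run; returns (coef, loglik, converged)."""
    n, k = D.shape
    coef = np.zeros(k)
    # sensible intercept start
    ybar = np.clip(np.mean(y), _PROB_EPS, 1.0 - _PROB_EPS)
    coef[0] = np.log(ybar / (1.0 - ybar))
    penalty = ridge * np.eye(k)
    penalty[0, 0] = 0.0  # never penalize the intercept
    ll_old = -np.inf
    converged = False
    for _ in range(_IRLS_MAX_ITER):
        p = _sigmoid(D @ coef)
        ll = float(np.sum(bernoulli_loglik_vector(y, p))) - 0.5 * ridge * float(
            coef[1:] @ coef[1:]
        )
        w = p * (1.0 - p)
        grad = D.T @ (y - p) - penalty @ coef
        hess = (D * w[:, None]).T @ D + penalty
        try:
            step = np.linalg.solve(hess + _DESIGN_JITTER * np.eye(k), grad)
        except np.linalg.LinAlgError:
            return coef, ll, False
        if not np.all(np.isfinite(step)):
            return coef, ll, False
        # step-halving keeps the likelihood non-decreasing under separation
        factor = 1.0
        for _ in range(30):
            new = coef + factor * step
            p_new = _sigmoid(D @ new)
            ll_new = float(np.sum(bernoulli_loglik_vector(y, p_new))) - 0.5 * ridge * float(
                new[1:] @ new[1:]
            )
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        coef = coef + factor * step
        if abs(ll_new - ll_old) < _IRLS_TOL:
            converged = True
            ll = ll_new
            break
        ll_old = ll_new
        ll = ll_new
    return coef, ll, converged


def fit_logistic(Z: np.ndarray, y: np.ndarray) -> LogisticFit:
    """Logistic MLE by Newton-IRLS.

    On non-convergence the fit is retried once with an L2 penalty of 1e-6 on
    the slope coefficients and flagged; callers comparing nested models must
    use the same penalty on both (see :func:`fit_logistic_pair`).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if Z is None or np.size(Z) == 0:
        Z = np.empty((n, 0))
    D = _design(Z)
    coef, ll, converged = _irls(D, y, ridge=0.0)
    flagged = False
    if not converged:
        coef, ll, converged = _irls(D, y, ridge=_IRLS_RIDGE)
        flagged = True
    # (quasi-)separation: slopes diverge, likelihood is effectively capped
    if coef[1:].size and np.max(np.abs(coef[1:])) > 15.0:
        flagged = True
    p = _sigmoid(D @ coef)
    loglik = float(np.sum(bernoulli_loglik_vector(y, p)))
    return LogisticFit(coef=coef, loglik=loglik, converged=converged, flagged=flagged)


def fit_logistic_pair(Z_small, Z_big, y) -> tuple:
    """Fit nested logistic models with a shared penalty policy.

    If either unpenalized fit fails to converge, both are refit with the same
    small L2 penalty so the likelihood-ratio statistic compares like with
    like, and both fits are flagged.
    """
    small = fit_logistic(Z_small, y)
    big = fit_logistic(Z_big, y)
    if small.flagged or big.flagged:
        y = np.asarray(y, dtype=float)
        n = y.shape[0]
        Ds = _design(Z_small if Z_small is not None and np.size(Z_small) else np.empty((n, 0)))
        Db = _design(Z_big if Z_big is not None and np.size(Z_big) else np.empty((n, 0)))
        coef_s, _, _ = _irls(Ds, y, ridge=_IRLS_RIDGE)
        coef_b, _, _ = _irls(Db, y, ridge=_IRLS_RIDGE)
        small = LogisticFit(
            coef=coef_s,
            loglik=float(np.sum(bernoulli_loglik_vector(y, _sigmoid(Ds @ coef_s)))),
            converged=True,
            flagged=True,
        )
        big = LogisticFit(
            coef=coef_b,
            loglik=float(np.sum(bernoulli_loglik_vector(y, _sigmoid(Db @ coef_b)))),
            converged=True,
            flagged=True,
        )
    return small, big
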