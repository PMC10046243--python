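"""Independent logistic-regression oracle for cross-checking fits.

A plain Newton/IRLS maximiser with step-halving, written directly from the
likelihood — deliberately not sharing any code path with the package's
statsmodels-backed fitter.
"""

import numpy as np


def logistic_loglike(beta, y, X):
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def irls_logit(y, X, tol=1e-10, maxiter=200):
    """Return (beta, llf, bse) for a maximum-likelihood logistic fit."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    ll = logistic_loglike(beta, y, X)
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu)
        hess = X.T @ (w[:, None] * X)
        step = np.linalg.solve(hess, grad)
        t = 1.0
        while t > 1e-10:
            cand_ll = logistic_loglike(beta + t * step, y, X)
            if cand_ll >= ll - 1e-14:
                break
            t *= 0.5
        beta = beta + t * step
        new_ll = logistic_loglike(beta, y, X)
        if np.max(np.abs(t * step)) < tol and abs(new_ll - ll) < tol:
            ll = new_ll
            break
        ll = new_ll
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv(X.T @ (w[:, None] * X))
    return beta, ll, np.sqrt(np.diag(cov))


def oracle_bic(y, X):
    _, ll, _ = irls_logit(y, X)
    return -2.0 * ll + X.shape[1] * np.log(len(y))
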