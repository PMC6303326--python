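"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: closed-form normal
equations + analytic likelihood for the Gaussian GLM, hand-rolled IRLS for
the logit, and term-by-term scipy.stats evaluation for the hierarchical
joint density.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit, gammaln


def gaussian_glm_oracle(y: np.ndarray, X: np.ndarray) -> dict:
    """Normal-equations OLS with R-glm likelihood/AIC and z-tests."""
    n, p = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    aic = -2.0 * loglik + 2.0 * (p + 1)
    disp = rss / (n - p)
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * disp)
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return {"beta": beta, "se": se, "z": z, "p": pvals, "loglik": loglik, "aic": aic}


def irls_logit_oracle(y: np.ndarray, X: np.ndarray, tol: float = 1e-12, maxiter: int = 200) -> np.ndarray:
    """Maximum-likelihood logit coefficients by iteratively reweighted LS."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        mu = expit(X @ beta)
        w = mu * (1 - mu)
        z = X @ beta + (y - mu) / np.clip(w, 1e-12, None)
        WX = X * w[:, None]
        new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


def joint_log_density_oracle(model, params: dict) -> float:
    """Term-by-term joint log-density of the five-sub-model system.

    Densities are with respect to (coefficients, z, log sigma_u, log sigma)
    coordinates: half-normal SD priors carry their log-transform Jacobian.
    """
    total = 0.0
    for name, sub in model.submodels.items():
        p = params[name]
        intercept = float(p["intercept"])
        beta = np.asarray(p["beta"], dtype=float)
        eta = intercept + (sub.X @ beta if sub.p else 0.0)

        coefs = np.concatenate([[intercept], beta])
        total += float(
            np.sum(stats.norm.logpdf(coefs, 0.0, np.sqrt(sub.priors.slope_variance)))
        )

        if sub.has_re:
            sigma_u = float(p["sigma_u"])
            z = np.asarray(p["z"], dtype=float)
            eta = eta + (sigma_u * z)[sub.groups]
            total += float(np.sum(stats.norm.logpdf(z, 0.0, 1.0)))
            total += float(stats.halfnorm.logpdf(sigma_u, scale=sub.priors.re_sd_scale))
            total += np.log(sigma_u)  # Jacobian of the log-SD coordinate

        if sub.family == "normal":
            sigma = float(p["sigma"])
            total += float(np.sum(stats.norm.logpdf(sub.y, eta, sigma)))
            total += float(stats.halfnorm.logpdf(sigma, scale=sub.priors.resid_sd_scale))
            total += np.log(sigma)
        else:
            lam = np.exp(np.clip(eta, -50, 50))
            total += float(np.sum(sub.y * np.log(lam) - lam - gammaln(sub.y + 1.0)))
    return total
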