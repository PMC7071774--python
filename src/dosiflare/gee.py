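"""Generalized estimating equations for clustered longitudinal biomarkers.

Marginal normal model with identity link, exchangeable working correlation
and robust (sandwich) inference — the standard analysis for unbalanced
repeated measures with subjects as clusters.  For cluster i with n_i
observations, design X_i and outcome y_i:

    working covariance  V_i = phi * R(alpha),   R(alpha) = (1-alpha) I + alpha J
    quasi-score update  beta <- beta + (sum X_i' V_i^-1 X_i)^-1 sum X_i' V_i^-1 (y_i - X_i beta)

alpha (exchangeable correlation) and phi (dispersion) are moment-estimated
from Pearson residuals between beta updates; iteration stops when the beta
step falls below tolerance.  Standard errors come from the sandwich
estimator

    cov(beta) = B^-1 M B^-1,  B = sum X_i' V_i^-1 X_i,
                              M = sum X_i' V_i^-1 e_i e_i' V_i^-1 X_i

which is consistent even when the working correlation is misspecified.
With every cluster of size one the estimator reduces exactly to ordinary
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GEEFit", "ContrastResult", "fit_gee", "contrast", "bonferroni_level"]


@dataclass
class GEEFit:
    """Fitted GEE: coefficients, working-correlation state, robust covariance."""

    params: pd.Series  # beta, indexed by design column names
    alpha: float  # exchangeable correlation estimate
    phi: float  # dispersion
    robust_cov: pd.DataFrame  # sandwich covariance of beta
    converged: bool
    n_clusters: int
    n_obs: int
    n_iter: int

    def bse(self) -> pd.Series:
        """Robust (sandwich) standard errors."""
        return pd.Series(
            np.sqrt(np.diag(self.robust_cov.to_numpy())), index=self.params.index
        )


@dataclass(frozen=True)
class ContrastResult:
    """Wald test of a linear combination w' beta with robust variance."""

    estimate: float
    se: float
    z: float
    p: float
    level: float
    significant: bool


def _split_clusters(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    Xo, yo, go = X[order], y[order], groups[order]
    _, starts = np.unique(go, return_index=True)
    bounds = np.append(np.sort(starts), len(go))
    return [(Xo[a:b], yo[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]


def fit_gee(
    X,
    y,
    groups,
    columns=None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> GEEFit:
    """Fit the identity-link normal GEE with exchangeable working correlation.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Design matrix; must be full column rank (aliased columns are named in
        the error).
    y : (n,) array
        Outcome; must be finite.
    groups : (n,) array
        Cluster labels (subjects); at least two clusters.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if columns is None:
        columns = [f"x{j}" for j in range(X.shape[1])]
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 clusters")
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify aliased columns from the QR diagonal
        _, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0])
        aliased = [columns[j] for j in range(p) if not keep[j]]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")

    clusters = _split_clusters(X, y, groups)
    max_n = max(len(yi) for _, yi in clusters)

    # initialize at OLS
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    alpha, phi = 0.0, 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # moment estimates of phi and alpha from Pearson residuals
        resid = [yi - Xi @ beta for Xi, yi in clusters]
        phi = sum(float(e @ e) for e in resid) / (n - p)
        num, n_pairs = 0.0, 0
        for e in resid:
            ni = len(e)
            if ni > 1:
                s = e.sum()
                num += 0.5 * (s * s - float(e @ e))
                n_pairs += ni * (ni - 1) // 2
        if n_pairs > p and phi > 0:
            alpha = num / ((n_pairs - p) * phi)
            alpha = float(np.clip(alpha, -1.0 / max(max_n - 1, 1) + 1e-6, 1 - 1e-6))
        else:
            alpha = 0.0

        # quasi-scoring beta update
        B = np.zeros((p, p))
        u = np.zeros(p)
        for Xi, yi in clusters:
            ni = len(yi)
            R = (1 - alpha) * np.eye(ni) + alpha * np.ones((ni, ni))
            Vinv = np.linalg.inv(phi * R)
            XtV = Xi.T @ Vinv
            B += XtV @ Xi
            u += XtV @ (yi - Xi @ beta)
        step = np.linalg.solve(B, u)
        beta = beta + step
        if np.linalg.norm(step) < tol:
            converged = True
            break

    # sandwich covariance at the final estimate
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    for Xi, yi in clusters:
        ni = len(yi)
        R = (1 - alpha) * np.eye(ni) + alpha * np.ones((ni, ni))
        Vinv = np.linalg.inv(phi * R)
        XtV = Xi.T @ Vinv
        e = yi - Xi @ beta
        B += XtV @ Xi
        g = XtV @ e
        M += np.outer(g, g)
    Binv = np.linalg.inv(B)
    cov = Binv @ M @ Binv
    cov = 0.5 * (cov + cov.T)
    return GEEFit(
        params=pd.Series(beta, index=columns),
        alpha=float(alpha),
        phi=float(phi),
        robust_cov=pd.DataFrame(cov, index=columns, columns=columns),
        converged=converged,
        n_clusters=len(clusters),
        n_obs=n,
        n_iter=it,
    )


def contrast(fit: GEEFit, weights, level: float = 0.05) -> ContrastResult:
    """Wald test of w' beta using the robust covariance.

    ``weights`` may be a vector aligned with the coefficient order or a
    mapping {name: weight} over a subset of coefficients.
    """
    if isinstance(weights, dict):
        w = pd.Series(0.0, index=fit.params.index)
        for k, v in weights.items():
            w[k] = v
        w = w.to_numpy()
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (len(fit.params),):
        raise ValueError(f"weights must have length {len(fit.params)}")
    est = float(w @ fit.params.to_numpy())
    var = float(w @ fit.robust_cov.to_numpy() @ w)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0:
        z, p = 0.0, 1.0
    else:
        z = est / se
        p = float(2 * sps.norm.sf(abs(z)))
    return ContrastResult(est, se, z, p, level, bool(p < level))


def bonferroni_level(family_alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison significance level alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return family_alpha / m
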