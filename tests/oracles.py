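"""Independent reference implementations used only as test oracles.

Each function here is written from the underlying definitions, separately
from the package code paths it checks: a brute-force evaluation of the
two-source diffusion Green's function, a grid-search scattering power fit, a
bounded-least-squares unmixer, an exhaustive rank-sum null distribution, and
the closed-form posterior of a one-dimensional two-Gaussian classifier.
"""

from __future__ import annotations

import cmath
import itertools
import math

import numpy as np
from scipy.integrate import quad


def oracle_reff(n_in: float, n_out: float) -> float:
    """Effective reflection coefficient via integrals over mu = cos(theta)."""
    if n_in == n_out:
        return 0.0
    n = n_in / n_out

    def fresnel(mu: float) -> float:
        sin_i = math.sqrt(max(1.0 - mu * mu, 0.0))
        sin_t = n * sin_i
        if sin_t >= 1.0:
            return 1.0
        cos_t = math.sqrt(1.0 - sin_t * sin_t)
        rs = (n * mu - cos_t) / (n * mu + cos_t)
        rp = (n * cos_t - mu) / (n * cos_t + mu)
        return 0.5 * (rs * rs + rp * rp)

    mu_c = math.sqrt(max(1.0 - 1.0 / (n * n), 0.0))  # cos of the critical angle
    r_phi = sum(
        quad(lambda m: 2.0 * m * fresnel(m), a, b, limit=200)[0]
        for a, b in ((0.0, mu_c), (mu_c, 1.0))
    )
    r_j = sum(
        quad(lambda m: 3.0 * m * m * fresnel(m), a, b, limit=200)[0]
        for a, b in ((0.0, mu_c), (mu_c, 1.0))
    )
    return (r_phi + r_j) / (2.0 - r_phi + r_j)


def oracle_fd_reflectance(
    mua: float, musp: float, rho: float, n_in: float, n_out: float, f_mhz: float
) -> complex:
    """Brute-force two-source Green's function, written from the definitions."""
    mutr = mua + musp
    D = 1.0 / (3.0 * mutr)
    v = 299.792458 / n_in  # mm / ns
    omega = 2.0 * math.pi * f_mhz * 1e-3  # rad / ns
    k = cmath.sqrt(complex(mua, omega / v) / D)
    if k.real < 0:
        k = -k
    z0 = 1.0 / mutr
    zb = 2.0 * D * (1.0 + oracle_reff(n_in, n_out)) / (1.0 - oracle_reff(n_in, n_out))
    r1 = math.hypot(rho, z0)
    r2 = math.hypot(rho, z0 + 2.0 * zb)
    return (cmath.exp(-k * r1) / r1 - cmath.exp(-k * r2) / r2) / (4.0 * math.pi * D)


def oracle_scatter_power_b(wavelengths, musp_values, lambda_ref=800.0, b_grid=None):
    """Grid-search estimate of the scattering power b (A profiled per b)."""
    wl = np.asarray(wavelengths, float)
    mu = np.asarray(musp_values, float)
    b_grid = np.linspace(0.0, 3.0, 30001) if b_grid is None else b_grid
    best_b, best_cost = None, np.inf
    x = np.log(wl / lambda_ref)
    y = np.log(mu)
    for b in b_grid:
        log_a = np.mean(y + b * x)  # least squares over log A at fixed b
        cost = float(np.sum((y - (log_a - b * x)) ** 2))
        if cost < best_cost:
            best_b, best_cost = b, cost
    return best_b


def oracle_nnls(design, target):
    """Nonnegative least squares via bounded trust-region solver."""
    from scipy.optimize import lsq_linear

    res = lsq_linear(design, target, bounds=(0, np.inf), tol=1e-14)
    return res.x


def oracle_ranksum_exact_p(a, b) -> float:
    """Two-sided exact rank-sum p value by full enumeration (tie-free data)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n, m = len(a), len(b)
    mean_w = n * (n + m + 1) / 2
    all_ranks = list(range(1, n + m + 1))
    count = 0
    total = 0
    for comb in itertools.combinations(all_ranks, n):
        w = sum(comb)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def oracle_lda_posterior_1d(x, mu0, mu1, sigma2, prior1) -> float:
    """Closed-form posterior of class 1 for the equal-variance 1-D Gaussian model.

    P(1|x) = logistic( (mu1-mu0)/s2 * x - (mu1^2-mu0^2)/(2 s2) + log(p1/p0) )
    """
    a = (mu1 - mu0) / sigma2
    c = -(mu1 * mu1 - mu0 * mu0) / (2.0 * sigma2) + math.log(prior1 / (1.0 - prior1))
    t = a * x + c
    return 1.0 / (1.0 + math.exp(-t))


def oracle_auc_mannwhitney(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic over positive/negative score pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))
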