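"""Negative-binomial numerics shared by the dispersion estimator and the LRT.

Parameterization: NB(mu, alpha) has mean ``mu`` and variance ``mu + alpha*mu^2``
(``alpha`` is the dispersion; ``alpha -> 0`` is the Poisson limit).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

__all__ = ["nb_logpmf", "nb_rvs", "fit_mu", "nb_pseudocounts"]

_POISSON_ALPHA = 1e-8  # below this, dispatch to the Poisson limit


def nb_logpmf(x, mu, alpha):
    """Numerically stable log pmf of NB(mu, alpha) at (possibly real) x.

    Real-valued x (pseudocounts) are admitted via log-Gamma.  ``alpha == 0``
    dispatches to the Poisson pmf.  ``mu == 0`` gives a point mass at zero.
    """
    x, mu, alpha = np.broadcast_arrays(*np.atleast_1d(x, mu, alpha))
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any((mu <= 0) & (x > 0) & np.isfinite(x)):
        raise ValueError("mu <= 0 with positive count")
    out = np.full(x.shape, -np.inf)
    zero = mu <= 0
    out[zero & (x == 0)] = 0.0
    pois = (~zero) & (alpha < _POISSON_ALPHA)
    if pois.any():
        out[pois] = x[pois] * np.log(mu[pois]) - mu[pois] - gammaln(x[pois] + 1)
    nb = (~zero) & ~pois
    if nb.any():
        a, m, xx = alpha[nb], mu[nb], x[nb]
        inv = 1.0 / a
        out[nb] = (gammaln(xx + inv) - gammaln(xx + 1) - gammaln(inv)
                   - inv * np.log1p(a * m)
                   + xx * (np.log(a * m) - np.log1p(a * m)))
    return out if out.shape else float(out)


def nb_rvs(mu, alpha, rng):
    """Draw NB(mu, alpha) variates elementwise; NaN means propagate to NaN."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.full(mu.shape, np.nan)
    ok = np.isfinite(mu)
    pois = ok & (alpha < _POISSON_ALPHA)
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ok & ~pois
    if nb.any():
        n = 1.0 / alpha[nb]
        p = n / (n + mu[nb])
        out[nb] = rng.negative_binomial(n, p)
    return out


def _mu_score(logmu, x, k, alpha):
    """Score (up to the positive factor 1/mu) of the NB log-likelihood in mu.

    Observations x with scalings k and dispersions alpha share a single mu:
    g = sum_r [x_r - (alpha_r x_r + 1) mu k_r / (1 + alpha_r mu k_r)],
    valid for alpha_r = 0 as well.  Monotone decreasing in mu.
    """
    mu = np.exp(logmu)
    mk = mu[..., None] * k
    return (x - (alpha * x + 1.0) * mk / (1.0 + alpha * mk)).sum(axis=-1)


def fit_mu(x, k, alpha, lo=1e-9, hi=1e12, iters=64):
    """Vectorized ML estimate of the shared NB mean over the trailing axis.

    Parameters
    ----------
    x : array (..., R) of counts (real pseudocounts allowed).
    k : array (..., R) of multiplicative scaling factors (> 0).
    alpha : array broadcastable to x; per-observation dispersion (0 = Poisson).

    Returns mu with shape ``x.shape[:-1]``; rows with all-zero counts get 0.
    The score is monotone in log mu, so a plain bisection is exact and robust.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), x.shape)
    total = x.sum(axis=-1)
    a = np.full(total.shape, np.log(lo))
    b = np.full(total.shape, np.log(hi))
    for _ in range(iters):
        mid = 0.5 * (a + b)
        high = _mu_score(mid, x, k, alpha) > 0
        a = np.where(high, mid, a)
        b = np.where(high, b, mid)
    mu = np.exp(0.5 * (a + b))
    return np.where(total > 0, mu, 0.0)


def _cdf(x, mu, alpha):
    if alpha < _POISSON_ALPHA:
        return poisson.cdf(x, mu)
    n = 1.0 / alpha
    return nbinom.cdf(x, n, n / (n + mu))


def _mid_cdf(m, mu, alpha):
    """Continuity-corrected CDF at integer m: (F(m-1) + F(m)) / 2."""
    return 0.5 * (_cdf(m - 1.0, mu, alpha) + _cdf(m, mu, alpha))


def nb_pseudocounts(x, mu_source, mu_target, alpha, max_steps=200):
    """Quantile-map counts between NB distributions of equal dispersion.

    ``x`` observed under NB(mu_source, alpha) is mapped to the equivalent
    quantile of NB(mu_target, alpha) using mid-p CDF matching, with the
    inverse mid-CDF linearly interpolated between consecutive integers so the
    returned pseudocounts are continuous.  When source and target coincide
    the map is the identity.
    """
    x = np.asarray(x, dtype=float)
    mu_source = np.broadcast_to(np.asarray(mu_source, dtype=float), x.shape)
    mu_target = np.broadcast_to(np.asarray(mu_target, dtype=float), x.shape)
    if np.allclose(mu_source, mu_target, rtol=1e-12, atol=0):
        return x.copy()
    u = _mid_cdf(x, mu_source, alpha)
    # normal-approximation initial guess for the target integer bracket
    sd_s = np.sqrt(mu_source * (1 + alpha * mu_source))
    sd_t = np.sqrt(mu_target * (1 + alpha * mu_target))
    m = np.floor(mu_target + sd_t / np.maximum(sd_s, 1e-30)
                 * (x + 0.5 - mu_source) - 0.5)
    m = np.maximum(m, -1.0)
    gm = _mid_cdf(m, mu_target, alpha)
    gm1 = _mid_cdf(m + 1, mu_target, alpha)
    for _ in range(max_steps):
        up = gm1 <= u
        down = (gm > u) & ~up & (m >= 0)
        if not (up.any() or down.any()):
            break
        m = m + up - down
        move = up | down
        gm = np.where(move, _mid_cdf(m, mu_target, alpha), gm)
        gm1 = np.where(move, _mid_cdf(m + 1, mu_target, alpha), gm1)
    denom = np.maximum(gm1 - gm, 1e-300)
    frac = np.clip((u - gm) / denom, 0.0, 1.0)
    return np.maximum(m + frac, 0.0)
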