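"""Mean-variance modeling and simulation of quantile-normalized 5C counts.

Within each condition, per-interaction sample moments are pooled across
regions into overlapping distance windows (finer windows at short range where
the signal changes quickly), the dispersion of the quadratic mean-variance
relationship sigma^2 = A mu^2 + mu is fit per window, smoothed along distance
by LOWESS, and blended with the observed per-interaction variance.  Simulated
pseudoreplicates are NB draws parameterized by (mean, blended variance); they
provide the null replicate sets for empirical FDR estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = ["FiveCDataset", "mvr_windows", "sample_moments", "fit_mvr",
           "fit_window_dispersion", "MVRModel", "blend_variance",
           "simulate_5c_replicates", "simulate_null_set",
           "make_synthetic_5c_baseline"]

# (regime start bp, regime end bp, window size bp, step bp)
MVR_REGIMES = ((0, 150_000, 12_000, 4_000),
               (150_000, 600_000, 24_000, 8_000),
               (600_000, 1_000_000, 60_000, 24_000))


@dataclass
class FiveCDataset:
    """Fragment-level quantile-normalized count matrices.

    ``counts[condition][region]`` is an array (n_reps, n_frags, n_frags),
    symmetric with the diagonal ignored; ``midpoints[region]`` gives fragment
    midpoints in bp.
    """

    midpoints: dict
    counts: dict
    conditions: tuple

    @property
    def regions(self):
        return list(self.midpoints)

    def n_reps(self, condition):
        first = self.counts[condition][self.regions[0]]
        return first.shape[0]

    def distance_matrix(self, region):
        m = self.midpoints[region]
        return np.abs(m[:, None] - m[None, :])


def mvr_windows(regimes=MVR_REGIMES):
    """Sliding distance windows [(start, end) bp] over the three regimes;
    windows straddling a regime boundary belong to the regime of their start."""
    windows = []
    for lo, hi, size, step in regimes:
        for s in range(lo, hi, step):
            windows.append((float(s), float(s + size)))
    return windows


def sample_moments(data: FiveCDataset, condition):
    """Per-interaction sample mean and unbiased variance across replicates."""
    mu, var = {}, {}
    for region in data.regions:
        c = data.counts[condition][region]
        if c.shape[0] < 2:
            raise ValueError("moments need >= 2 replicates")
        mu[region] = c.mean(axis=0)
        var[region] = c.var(axis=0, ddof=1)
    return mu, var


def fit_window_dispersion(mu, var):
    """Non-negative least-squares dispersion of sigma^2 = A mu^2 + mu over
    one window: A = max(0, sum((sigma^2 - mu) mu^2) / sum(mu^4))."""
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    return max(0.0, float(((var - mu) * mu ** 2).sum() / (mu ** 4).sum()))


@dataclass
class MVRModel:
    condition: str
    windows: list
    window_dist: np.ndarray      # representative (median member) distance
    A_raw: np.ndarray            # per-window fit, NaN when underdetermined
    A_smooth: np.ndarray         # LOWESS-smoothed, clamped >= 0
    alpha_w: float = 0.5         # weight of the predicted variance
    beta_w: float = 0.5          # weight of the observed variance
    max_dist: float = field(default=1_000_000.0)

    def window_for(self, dist):
        """Index of the window whose centre is nearest; distances beyond the
        last regime use the outermost window."""
        centers = np.array([(a + b) / 2 for (a, b) in self.windows])
        dist = np.atleast_1d(np.asarray(dist, dtype=float))
        idx = np.abs(dist[:, None] - centers[None, :]).argmin(axis=1)
        idx[dist > self.max_dist] = len(self.windows) - 1
        return idx

    def predicted_variance(self, mu, dist):
        A = self.A_smooth[self.window_for(np.ravel(dist))].reshape(np.shape(mu))
        return A * np.asarray(mu) ** 2 + np.asarray(mu)


def fit_mvr(data: FiveCDataset, condition, alpha_w: float = 0.5,
            beta_w: float = 0.5, lowess_frac: float = 0.5,
            min_points: int = 3) -> MVRModel:
    """Fit the per-window dispersion A of sigma^2 = A mu^2 + mu.

    Interactions with mean <= 1 or mean more than 2.5 SD above the window's
    mean of means are excluded from the fit.  A is the non-negative least
    squares solution of (sigma^2 - mu) = A mu^2 through the origin.
    """
    mus, vars_, dists = [], [], []
    mu_m, var_m = sample_moments(data, condition)
    for region in data.regions:
        dm = data.distance_matrix(region)
        iu = np.triu_indices_from(dm, k=1)
        mus.append(mu_m[region][iu])
        vars_.append(var_m[region][iu])
        dists.append(dm[iu])
    mu = np.concatenate(mus)
    var = np.concatenate(vars_)
    dist = np.concatenate(dists)

    windows = mvr_windows()
    A = np.full(len(windows), np.nan)
    wdist = np.array([(a + b) / 2 for (a, b) in windows])
    for wi, (a, b) in enumerate(windows):
        sel = (dist >= a) & (dist < b)
        if not sel.any():
            continue
        m, v = mu[sel], var[sel]
        keep = (m > 1) & (m <= m.mean() + 2.5 * m.std())
        if keep.sum() < min_points:
            continue
        m, v = m[keep], v[keep]
        A[wi] = fit_window_dispersion(m, v)
        wdist[wi] = float(np.median(dist[sel][keep]))
    ok = np.isfinite(A)
    if ok.sum() >= 2:
        A_smooth = sm.nonparametric.lowess(A[ok], wdist[ok], frac=lowess_frac,
                                           it=0, xvals=wdist)
    elif ok.sum() == 1:
        A_smooth = np.full(len(windows), A[ok][0])
    else:
        raise ValueError("no window had enough interactions to fit the MVR")
    A_smooth = np.maximum(A_smooth, 0.0)
    return MVRModel(condition, windows, wdist, A, A_smooth, alpha_w, beta_w)


def blend_variance(predicted, observed, alpha_w: float = 0.5,
                   beta_w: float = 0.5, mu=None):
    """Weighted blend of predicted and observed variances; clamped to at
    least the mean so an NB distribution is parameterizable."""
    if alpha_w < 0 or beta_w < 0:
        raise ValueError("blend weights must be non-negative")
    out = alpha_w * np.asarray(predicted) + beta_w * np.asarray(observed)
    if mu is not None:
        out = np.maximum(out, np.asarray(mu) * (1 + 1e-9))
    return out


def _nb_mean_var_draw(mu, var, rng):
    """Symmetric NB draws parameterized by (mean, variance); Poisson when the
    variance collapses to the mean, deterministic 0 when the mean is 0."""
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    out = np.zeros_like(mu)
    pos = mu > 0
    pois = pos & (var <= mu * (1 + 1e-9))
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = pos & ~pois
    if nb.any():
        size = mu[nb] ** 2 / (var[nb] - mu[nb])
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_5c_replicates(mu, var, n_sim: int, rng):
    """Draw ``n_sim`` symmetric simulated replicate matrices from NB(mu, var)."""
    n = mu.shape[0]
    iu = np.triu_indices(n, k=1)
    out = np.zeros((n_sim, n, n))
    for s in range(n_sim):
        vals = _nb_mean_var_draw(mu[iu], var[iu], rng)
        out[s][iu] = vals
        out[s].T[iu] = vals
    return out


def simulate_null_set(data: FiveCDataset, condition, n_replicates: int = 6,
                      alpha_w: float = 0.5, beta_w: float = 0.5,
                      seed=None) -> dict:
    """Simulate a same-condition null replicate set (region -> stack).

    The chosen condition should normally be the one with the highest fitted
    dispersion, which gives the most conservative empirical FDR.
    """
    rng = np.random.default_rng(seed)
    model = fit_mvr(data, condition, alpha_w, beta_w)
    mu_m, var_m = sample_moments(data, condition)
    out = {}
    for region in data.regions:
        mu = mu_m[region]
        pred = model.predicted_variance(mu, data.distance_matrix(region))
        var = blend_variance(pred, var_m[region], alpha_w, beta_w, mu=mu)
        out[region] = simulate_5c_replicates(mu, var, n_replicates, rng)
    return out


def mean_fitted_dispersion(data: FiveCDataset) -> dict:
    """Mean smoothed MVR dispersion per condition (used to pick the default
    null-generating condition)."""
    return {c: float(np.nanmean(fit_mvr(data, c).A_smooth))
            for c in data.conditions}


def make_synthetic_5c_baseline(n_frags: int = 100, n_regions: int = 1,
                               conditions=("A", "B", "C"), n_reps: int = 2,
                               frag_spacing: float = 4_000.0,
                               n_loops_per_class: int = 2,
                               loop_boost: float = 3.0, seed=None):
    """Synthetic fragment-level 5C counts for testing: power-law distance
    decay, overdispersion rising toward short distances, and planted
    condition-specific loop foci for every nonempty proper subset of the
    condition set.

    Returns (FiveCDataset, truth) where truth is a list of
    (region, frozenset of (i, j) fragment pairs, frozenset of conditions).
    """
    rng = np.random.default_rng(seed)
    conditions = tuple(conditions)
    classes = [frozenset([c]) for c in conditions]
    if len(conditions) == 3:
        classes += [frozenset(pair) for pair in
                    [(conditions[0], conditions[1]),
                     (conditions[0], conditions[2]),
                     (conditions[1], conditions[2])]]
    midpoints, counts, truth = {}, {c: {} for c in conditions}, []
    for ri in range(n_regions):
        region = f"region_{ri}"
        mids = (np.arange(n_frags) * frag_spacing
                + rng.uniform(-0.1, 0.1, n_frags) * frag_spacing)
        midpoints[region] = np.sort(mids)
        dm = np.abs(mids[:, None] - mids[None, :])
        base = 2000.0 / np.maximum(dm / 1000.0, 1.0) ** 0.8
        np.fill_diagonal(base, 0.0)
        boost = {c: np.ones_like(base) for c in conditions}
        occupied = set()
        for cls in classes:
            for _ in range(n_loops_per_class):
                for _attempt in range(200):
                    i = int(rng.integers(0, n_frags - 2))
                    j = int(rng.integers(0, n_frags - 2))
                    i, j = min(i, j), max(i, j)
                    d = abs(mids[j] - mids[i])
                    if not 30_000 <= d <= 300_000:
                        continue
                    block = {(i + a, j + b) for a in range(2) for b in range(2)}
                    if any(b_ in occupied for b_ in block):
                        continue
                    occupied |= block
                    for c in cls:
                        for (bi, bj) in block:
                            boost[c][bi, bj] = loop_boost
                            boost[c][bj, bi] = loop_boost
                    truth.append((region, frozenset(block), cls))
                    break
        for c in conditions:
            m = base * boost[c]
            A = 0.02 + 0.10 * np.exp(-dm / 150_000.0)
            var = A * m ** 2 + m
            counts[c][region] = simulate_5c_replicates(m, var, n_reps, rng)
    return FiveCDataset(midpoints, counts, conditions), truth
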