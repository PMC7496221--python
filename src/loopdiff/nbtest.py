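"""Per-pixel negative-binomial likelihood-ratio test, FDR control, clustering
and classification of differential looping interactions.

The null model fits one shared interaction strength mu_0 per pixel across all
conditions; the alternative fits one mu_c per condition.  Bias, size factors
and dispersion are nuisance parameters held fixed.  -2 log lambda is referred
to a chi-square with |C| - 1 degrees of freedom.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .core import StudyDesign
from .nb import fit_mu, nb_logpmf

__all__ = ["lrt_pixels", "bh_fdr", "cluster_pixels", "classify_pixels",
           "sample_variance_alpha"]


def lrt_pixels(x, k, alpha, cond_index, n_conditions):
    """Likelihood-ratio test for equal interaction strength across conditions.

    Parameters
    ----------
    x, k : arrays (n_pixels, n_reps)
        Raw counts and combined scaling factors b_i * b_j * s_d per replicate.
    alpha : array (n_pixels, n_reps)
        Fixed dispersion per observation (condition- and distance-specific;
        zeros mean Poisson).
    cond_index : array (n_reps,)
        Condition index of each replicate column.
    n_conditions : int

    Returns
    -------
    stat, p, mu0, mu_alt
        LRT statistic (clipped at 0), right-tail chi-square p-value with
        ``n_conditions - 1`` df, and the fitted null / per-condition means
        (``mu_alt`` has shape (n_pixels, n_conditions)).
    """
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    n_pix = x.shape[0]
    mu0 = fit_mu(x, k, alpha)
    ll_null = nb_logpmf(x, mu0[:, None] * k, alpha).sum(axis=1)
    ll_alt = np.zeros(n_pix)
    mu_alt = np.zeros((n_pix, n_conditions))
    for c in range(n_conditions):
        cols = np.flatnonzero(cond_index == c)
        mu_c = fit_mu(x[:, cols], k[:, cols], alpha[:, cols])
        mu_alt[:, c] = mu_c
        ll_alt += nb_logpmf(x[:, cols], mu_c[:, None] * k[:, cols],
                            alpha[:, cols]).sum(axis=1)
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = chi2.sf(stat, df=n_conditions - 1)
    all_zero = x.sum(axis=1) == 0
    stat[all_zero] = 0.0
    p[all_zero] = 1.0
    return stat, p, mu0, mu_alt


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def cluster_pixels(pixels, min_size: int = 3):
    """Connected components of pixels under 4-connectivity (shared edge in
    matrix space).  Returns (clusters, discarded) where clusters is a list of
    frozensets of size >= min_size and discarded the set of remaining pixels."""
    pix = set(map(tuple, pixels))
    parent = {p: p for p in pix}

    def find(p):
        root = p
        while parent[root] != root:
            root = parent[root]
        while parent[p] != root:
            parent[p], p = root, parent[p]
        return root

    for (i, j) in pix:
        for nb in ((i + 1, j), (i, j + 1)):
            if nb in pix:
                ra, rb = find((i, j)), find(nb)
                if ra != rb:
                    parent[ra] = rb
    comps = {}
    for p in pix:
        comps.setdefault(find(p), []).append(p)
    clusters, discarded = [], set()
    for members in comps.values():
        if len(members) >= min_size:
            clusters.append(frozenset(members))
        else:
            discarded.update(members)
    clusters.sort(key=lambda s: min(s))
    return clusters, discarded


def classify_pixels(pixel_class_means: dict, conditions) -> tuple:
    """Label each pixel with the condition of its highest normalized mean.

    ``pixel_class_means`` maps pixel -> sequence of per-condition means in
    design order.  Exact ties break deterministically toward the first
    condition in design order and are flagged.
    """
    labels, ties = {}, set()
    for pixel, means in pixel_class_means.items():
        means = np.asarray(means, dtype=float)
        best = int(np.argmax(means))
        if (means == means[best]).sum() > 1:
            ties.add(pixel)
        labels[pixel] = conditions[best]
    return labels, ties


def sample_variance_alpha(zbar, svar, floor: float = 1e-7):
    """Per-pixel NB dispersion matching a sample variance: (s^2 - m) / m^2,
    floored for parameterizability."""
    zbar = np.asarray(zbar, dtype=float)
    svar = np.asarray(svar, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (svar - zbar) / (zbar * zbar)
    return np.maximum(np.nan_to_num(a, nan=floor), floor)
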