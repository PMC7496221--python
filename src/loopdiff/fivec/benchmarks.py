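"""Parametric benchmark tests over interaction-score or z-score matrices.

One-way fixed-effects ANOVA with BH correction, and a likelihood-ratio test
under a unit-variance normal model for z-scores (which are standard normal
under the loop-calling null): the alternative fits one shift parameter per
condition, the null a single shared shift, so -2 log lambda is chi-square
with |C| - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, f as f_dist, norm

from ..nbtest import bh_fdr

__all__ = ["anova_bh", "lrt3d_z", "lrt3d_classify", "LRTZResult"]


def anova_bh(groups):
    """Vectorized one-way ANOVA across pixels.

    ``groups`` is a sequence of arrays (n_pixels, n_reps_c), one per
    condition.  Degenerate pixels are flagged: zero within-group variance
    with nonzero between-group variance gives p = 0; all values identical
    gives p = 1.

    Returns (F, p, q, flags) where flags marks degenerate pixels.
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    if len(groups) < 2 or any(g.shape[1] < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 conditions with >= 2 replicates")
    ns = np.array([g.shape[1] for g in groups])
    N = ns.sum()
    k = len(groups)
    means = np.stack([g.mean(axis=1) for g in groups], axis=1)
    grand = sum(g.sum(axis=1) for g in groups) / N
    ss_between = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = sum(((g - m[:, None]) ** 2).sum(axis=1)
                    for g, m in zip(groups, means.T))
    df1, df2 = k - 1, N - k
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
        p = f_dist.sf(F, df1, df2)
    zero_within = ss_within <= 0
    flags = zero_within
    p = np.where(zero_within & (ss_between > 0), 0.0, p)
    p = np.where(zero_within & (ss_between <= 0), 1.0, p)
    F = np.where(zero_within, np.inf, F)
    F = np.where(zero_within & (ss_between <= 0), 0.0, F)
    return F, p, bh_fdr(p), flags


@dataclass
class LRTZResult:
    mu_hat: np.ndarray    # (n_pixels, n_conditions) condition shift MLEs
    mu0: np.ndarray       # grand-mean shift under the null
    stat: np.ndarray      # T = -2 log lambda
    p: np.ndarray
    q: np.ndarray
    df: int
    skipped: np.ndarray   # pixels with non-finite z, excluded with a flag


def lrt3d_z(groups) -> LRTZResult:
    """Likelihood-ratio test of equal shift across conditions for unit-
    variance normal z-scores, computed by direct density evaluation (the
    closed form sum_c n_c (zbar_c - zbar)^2 is used as a test oracle)."""
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 conditions")
    n_pix = groups[0].shape[0]
    skipped = ~np.all([np.isfinite(g).all(axis=1) for g in groups], axis=0)
    mu_hat = np.stack([g.mean(axis=1) for g in groups], axis=1)
    N = sum(g.shape[1] for g in groups)
    mu0 = sum(g.sum(axis=1) for g in groups) / N
    ll_alt = sum(norm.logpdf(g, loc=m[:, None]).sum(axis=1)
                 for g, m in zip(groups, mu_hat.T))
    ll_null = sum(norm.logpdf(g, loc=mu0[:, None]).sum(axis=1) for g in groups)
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    df = k - 1
    p = chi2.sf(stat, df)
    stat[skipped] = np.nan
    p[skipped] = np.nan
    q = np.full(n_pix, np.nan)
    if (~skipped).any():
        q[~skipped] = bh_fdr(p[~skipped])
    return LRTZResult(mu_hat, mu0, stat, p, q, df, skipped)


def lrt3d_classify(result: LRTZResult, conditions, target_fdr: float = 0.02):
    """Assign classes from a three-condition LRT result.

    Pixels with q above the target are constitutive.  Significant pixels rank
    their condition means mu_A' > mu_B' > mu_C' and take class {A'} when the
    top gap exceeds the bottom gap, {A', B'} otherwise.  Rank ties break
    deterministically by design-condition order and are flagged.
    """
    conditions = list(conditions)
    if len(conditions) != 3:
        raise ValueError("class assignment requires exactly 3 conditions")
    labels, ties = [], []
    for row, qv in zip(result.mu_hat, result.q):
        if not np.isfinite(qv):
            labels.append("skipped")
            ties.append(False)
            continue
        if qv > target_fdr:
            labels.append("constitutive")
            ties.append(False)
            continue
        order = sorted(range(3), key=lambda idx: (-row[idx], idx))
        tie = len(set(np.round(row, 15))) < 3
        a, b, c = (conditions[i] for i in order)
        gap_top = abs(row[order[0]] - row[order[1]])
        gap_bottom = abs(row[order[1]] - row[order[2]])
        if gap_top > gap_bottom:
            labels.append(a)
        elif gap_top < gap_bottom:
            labels.append(f"{a}+{b}")
        else:
            labels.append(a)  # equal gaps: single-condition reading
            tie = True
        ties.append(tie)
    return np.array(labels, dtype=object), np.array(ties, dtype=bool)
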