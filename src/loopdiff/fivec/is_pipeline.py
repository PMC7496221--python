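"""Conversion of 5C count matrices into interaction scores.

Fragment matrices are balanced (equal scaled row sums), binned onto a regular
4-kb grid with 16-kb smoothing windows, corrected by the maximum of a local
donut and lower-left expected (both rescaled by the regional distance-decay
curve), modeled per region with a two-parameter log-logistic distribution of
observed/expected ratios, and the right-tail p-values transformed to
interaction scores IS = -10*log2(p) and z-scores Phi^-1(1 - p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisk, norm

from ..normalization import kr_balance

__all__ = ["balance_and_bin", "local_expected", "loglogistic_pvalues",
           "is_transform", "z_transform", "counts_to_scores", "ScoreMatrices"]

_TINY = np.finfo(float).tiny


def balance_and_bin(counts, midpoints, bin_size: float = 4_000.0,
                    smooth_span: float = 16_000.0, balance: bool = True):
    """Balance a fragment matrix and bin it onto a regular grid.

    ``B[k, l]`` is the arithmetic mean of balanced counts over fragment pairs
    whose midpoints fall within the ``smooth_span`` windows centred on grid
    bins ``k`` and ``l``; empty windows give NaN.  Returns (B, bin_centers).
    ``balance=False`` skips balancing (for already-balanced input).
    """
    counts = np.asarray(counts, dtype=float)
    midpoints = np.asarray(midpoints, dtype=float)
    span = midpoints.max() - midpoints.min()
    if span < bin_size:
        raise ValueError("region smaller than one bin")
    work = counts.copy()
    np.fill_diagonal(work, 0.0)
    if balance:
        bias = kr_balance(work, bias_bounds=(1e-6, 1e6))
        with np.errstate(invalid="ignore"):
            balanced = work / (bias[:, None] * bias[None, :])
    else:
        balanced = work
    start = np.floor(midpoints.min() / bin_size) * bin_size
    n_bins = int(np.floor((midpoints.max() - start) / bin_size)) + 1
    centers = start + np.arange(n_bins) * bin_size
    member = [np.flatnonzero(np.abs(midpoints - c) <= smooth_span / 2)
              for c in centers]
    B = np.full((n_bins, n_bins), np.nan)
    for k in range(n_bins):
        for l in range(k, n_bins):
            fi, fj = member[k], member[l]
            if fi.size == 0 or fj.size == 0:
                continue
            sub = balanced[np.ix_(fi, fj)]
            if k == l:
                mask = fi[:, None] != fj[None, :]
                vals = sub[mask]
            else:
                vals = sub.ravel()
            vals = vals[np.isfinite(vals)]
            if vals.size:
                B[k, l] = B[l, k] = vals.mean()
    return B, centers


def _footprint_offsets(p: int, w: int):
    """HiCCUPS-style donut and lower-left footprints for a pixel (k, l), l > k."""
    donut, lower_left = [], []
    for dk in range(-w, w + 1):
        for dl in range(-w, w + 1):
            if dk == 0 and dl == 0:
                continue
            if max(abs(dk), abs(dl)) > w:
                continue
            if max(abs(dk), abs(dl)) <= p:
                continue
            if dk == 0 or dl == 0:
                continue
            donut.append((dk, dl))
            if 1 <= dk <= w and -w <= dl <= -1 and not (dk <= p and dl >= -p):
                lower_left.append((dk, dl))
    return donut, lower_left


def local_expected(B, p: int = 2, w: int = 6, min_frac: float = 0.5):
    """Expected matrix: max of donut and lower-left local estimates, each
    scaled by the region's distance-decay curve.

    For each pixel, expected = (sum of observed over the footprint / sum of
    the decay expectation over the footprint) * decay at the pixel's own
    distance.  Pixels whose valid footprint falls below ``min_frac`` of the
    full footprint (e.g. at matrix edges) are masked.
    """
    if p >= w:
        raise ValueError("inner radius p must be smaller than outer radius w")
    B = np.asarray(B, dtype=float)
    n = B.shape[0]
    decay = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(B, offset=d)
        if np.isfinite(diag).any():
            decay[d] = np.nanmean(diag)
    dmat = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    decay_mat = decay[dmat]

    donut, lower_left = _footprint_offsets(p, w)
    out = {}
    for name, offsets in (("donut", donut), ("lower_left", lower_left)):
        obs_sum = np.zeros((n, n))
        dec_sum = np.zeros((n, n))
        n_valid = np.zeros((n, n))
        for (dk, dl) in offsets:
            ob = _shift(B, dk, dl)
            de = _shift(decay_mat, dk, dl)
            ok = np.isfinite(ob) & np.isfinite(de)
            obs_sum[ok] += ob[ok]
            dec_sum[ok] += de[ok]
            n_valid += ok
        with np.errstate(invalid="ignore", divide="ignore"):
            e = obs_sum / dec_sum * decay_mat
        e[n_valid < min_frac * len(offsets)] = np.nan
        e[dec_sum == 0] = np.nan
        out[name] = e
    # lower-left footprint is defined for l > k; mirror for the lower triangle
    ll = out["lower_left"]
    il = np.tril_indices(n, k=-1)
    ll[il] = ll.T[il]
    with np.errstate(invalid="ignore"):
        E = np.fmax(out["donut"], ll)
    return E


def _shift(m, dk, dl):
    """Matrix whose (k, l) entry is m[k+dk, l+dl] (NaN outside)."""
    n = m.shape[0]
    out = np.full_like(m, np.nan)
    ks = slice(max(0, -dk), min(n, n - dk))
    ls = slice(max(0, -dl), min(n, n - dl))
    out[ks, ls] = m[max(0, dk): min(n, n + dk), max(0, dl): min(n, n + dl)]
    return out


def loglogistic_pvalues(obs, exp, min_values: int = 50):
    """Right-tail p-values of observed/expected ratios under a two-parameter
    log-logistic distribution fit by maximum likelihood over the region."""
    obs = np.asarray(obs, dtype=float)
    exp = np.asarray(exp, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = obs / exp
    ok = np.isfinite(ratio) & (ratio > 0)
    vals = ratio[ok]
    if vals.size < min_values:
        raise ValueError(f"only {vals.size} usable ratios; log-logistic fit "
                         "needs at least " + str(min_values))
    c, _loc, scale = fisk.fit(vals, floc=0)
    P = np.full(ratio.shape, np.nan)
    P[ok] = fisk.sf(ratio[ok], c, loc=0, scale=scale)
    return P, (c, scale)


def is_transform(P):
    """Interaction score IS = -10 * log2(p); p = 0 clipped to the smallest
    positive double."""
    P = np.asarray(P, dtype=float)
    return -10.0 * np.log2(np.clip(P, _TINY, None))


def z_transform(P):
    """z-score Phi^-1(1 - p)."""
    return norm.isf(np.clip(np.asarray(P, dtype=float), _TINY, 1 - 1e-16))


@dataclass
class ScoreMatrices:
    B: np.ndarray
    E: np.ndarray
    P: np.ndarray
    IS: np.ndarray
    Z: np.ndarray
    bin_centers: np.ndarray


def counts_to_scores(counts, midpoints, bin_size: float = 4_000.0,
                     smooth_span: float = 16_000.0, p: int = 2, w: int = 6,
                     min_dist_bp: float = 20_000.0,
                     min_values: int = 50) -> ScoreMatrices:
    """Full conversion for one replicate matrix of one region; identical for
    real and simulated counts.  Pairs within ``min_dist_bp`` are masked
    before model fitting and never reappear downstream."""
    B, centers = balance_and_bin(counts, midpoints, bin_size, smooth_span)
    near = np.abs(centers[:, None] - centers[None, :]) < min_dist_bp
    B = B.copy()
    B[near] = np.nan
    E = local_expected(B, p=p, w=w)
    P, _params = loglogistic_pvalues(B, E, min_values=min_values)
    return ScoreMatrices(B, E, P, is_transform(P), z_transform(P), centers)
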