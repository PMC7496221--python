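"""Per-condition distance-dispersion relationship (DDR) estimation.

Counts at a common interaction distance are pooled and a single dispersion is
estimated per (condition, distance) by quantile-adjusted conditional maximum
likelihood (qCML): per-pixel means are fit by ML under the current dispersion,
raw counts are quantile-mapped onto the geometric-mean scaling of the
condition's replicates, and the dispersion is updated by maximizing the
conditional likelihood of the pseudocounts given their per-pixel sums.  The
raw per-distance estimates are then smoothed by a precision-weighted LOWESS,
with the raw estimates retained at the shortest distances where the trend is
still decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
import statsmodels.api as sm

from .core import StudyDesign
from .nb import fit_mu, nb_pseudocounts

__all__ = ["condition_means", "tested_mask", "qcml_dispersion", "smooth_ddr",
           "estimate_ddr", "DispersionCurve", "DispersionModel"]

ALPHA_BOUNDS = (1e-7, 10.0)


def condition_means(z: dict, design: StudyDesign) -> dict:
    """Arithmetic mean of normalized counts across replicates per condition."""
    out = {}
    for c in design.conditions:
        reps = design.replicates_of(c)
        if not reps:
            raise ValueError(f"condition {c!r} has no replicates")
        out[c] = np.mean([z[r] for r in reps], axis=0)
    return out


def tested_mask(zbar: dict, design: StudyDesign, zero_excluded=None,
                min_mean: float = 1.0) -> np.ndarray:
    """Pixels eligible for testing: finite normalized mean >= ``min_mean`` in
    every condition, within the tested distance range, and (when supplied)
    not excluded for having a zero raw count in some replicate."""
    stack = np.stack([zbar[c] for c in design.conditions])
    mask = np.isfinite(stack).all(axis=0) & (stack >= min_mean).all(axis=0)
    width = mask.shape[1]
    d = np.arange(width)
    mask &= (d >= design.min_dist_bins) & (d <= design.max_dist_bins)
    if zero_excluded is not None:
        mask &= ~zero_excluded
    return mask


def _cml_loglik(pseudo: np.ndarray, alpha: float) -> float:
    """Conditional log-likelihood of pseudocounts given per-pixel sums."""
    n, nrep = pseudo.shape
    phi = 1.0 / alpha
    return float(gammaln(pseudo + phi).sum()
                 + n * gammaln(nrep * phi)
                 - gammaln(pseudo.sum(axis=1) + nrep * phi).sum()
                 - n * nrep * gammaln(phi))


def _argmax_cml(pseudo, guess, bounds=ALPHA_BOUNDS, xatol=1e-6):
    """Maximize the conditional likelihood over alpha on a log scale, starting
    from a narrow bracket around ``guess`` and expanding toward ``bounds``
    when the optimum presses an endpoint."""
    lo_g, hi_g = np.log(bounds[0]), np.log(bounds[1])
    lo = max(lo_g, np.log(guess) - 2.0)
    hi = min(hi_g, np.log(guess) + 2.0)
    for _ in range(12):
        res = minimize_scalar(lambda t: -_cml_loglik(pseudo, np.exp(t)),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": xatol})
        t = res.x
        if t - lo < 2 * xatol and lo > lo_g:
            lo = max(lo_g, lo - 4.0)
        elif hi - t < 2 * xatol and hi < hi_g:
            hi = min(hi_g, hi + 4.0)
        else:
            break
    return float(np.exp(t))


def qcml_dispersion(x, k, alpha0: float = 0.01, tol: float = 1e-4,
                    max_iter: int = 60) -> float:
    """qCML dispersion for counts ``x`` (n_pixels, n_reps) with scalings ``k``.

    When all replicates share identical scaling factors the quantile map is
    the identity and the procedure reduces to exact conditional ML.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("qCML needs >= 2 replicates")
    kbar = np.exp(np.log(k).mean(axis=1))
    equal_k = np.allclose(k, kbar[:, None], rtol=1e-9, atol=0)
    alpha = alpha0
    for _ in range(max_iter):
        if equal_k:
            pseudo = x
        else:
            mu = fit_mu(x, k, alpha)
            pseudo = nb_pseudocounts(x, mu[:, None] * k,
                                     (mu * kbar)[:, None], alpha)
        new = _argmax_cml(pseudo, guess=alpha)
        done = abs(new - alpha) < tol
        alpha = new
        if done:
            break
    return alpha


@dataclass
class DispersionCurve:
    """One condition's DDR: raw estimates, smoothing diagnostics, final curve.

    All arrays are indexed by distance offset ``d - min_dist`` over
    ``[min_dist, max_dist]``.
    """

    min_dist: int
    max_dist: int
    alpha_raw: np.ndarray       # qCML estimates, NaN at gap distances
    alpha_filled: np.ndarray    # gaps linearly interpolated
    rolling_var: np.ndarray     # v
    weights: np.ndarray         # w = v^(-1/4)
    dup_weights: np.ndarray     # integer duplication weights (0 at gaps)
    smoothed: np.ndarray        # LOWESS fit g(d)
    d_star: int
    alpha_final: np.ndarray
    lowess_frac: float

    def alpha_at(self, d):
        d = np.asarray(d)
        idx = np.clip(d - self.min_dist, 0, self.max_dist - self.min_dist)
        return self.alpha_final[idx]


@dataclass
class DispersionModel:
    curves: dict  # condition -> DispersionCurve

    def alpha_at(self, condition, d):
        return self.curves[condition].alpha_at(d)

    def save(self, path):
        """Serialize all curves as TSV: condition, distance, raw, rolling
        variance, weight, smoothed, final."""
        with open(path, "w") as fh:
            fh.write("condition\tdistance\talpha_raw\trolling_var\tweight\t"
                     "smoothed\talpha_final\n")
            for c, cv in self.curves.items():
                for n, d in enumerate(range(cv.min_dist, cv.max_dist + 1)):
                    fh.write(f"{c}\t{d}\t{cv.alpha_raw[n]:.8g}\t"
                             f"{cv.rolling_var[n]:.8g}\t{cv.weights[n]:.8g}\t"
                             f"{cv.smoothed[n]:.8g}\t{cv.alpha_final[n]:.8g}\n")


def smooth_ddr(alpha_raw: np.ndarray, min_dist: int, max_dist: int,
               lowess_frac: float | None = None, window: int = 20,
               max_dup: int = 1000) -> DispersionCurve:
    """Precision-weighted LOWESS smoothing of raw per-distance dispersions.

    The precision of each raw estimate is gauged by a centred rolling sample
    variance (window ``window`` distances); where the window would roll off
    the edges, the left side is filled with the first interior value and the
    right side with the maximum interior value.  Weights are inverse variance
    to the 1/4 power, rescaled so the smallest is 1 and floored to integers;
    each point is duplicated that many times before a single-pass tricube
    LOWESS fit.  The raw estimates are kept verbatim below the first distance
    at which they start increasing (``d_star``).
    """
    alpha_raw = np.asarray(alpha_raw, dtype=float)
    n = max_dist - min_dist + 1
    if alpha_raw.shape[0] != n:
        raise ValueError("alpha_raw must cover [min_dist, max_dist]")
    if n < window:
        raise ValueError("fewer distances than the rolling window width")
    dists = np.arange(min_dist, max_dist + 1)
    defined = np.isfinite(alpha_raw)
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined dispersion estimates")
    filled = np.interp(dists, dists[defined], alpha_raw[defined])

    half = window // 2
    left_anchor = min_dist + half      # 14 for the default range
    right_anchor = max_dist - half + 1  # 491 for the default range
    v = np.full(n, np.nan)
    for d in range(left_anchor, right_anchor + 1):
        seg = filled[d - half - min_dist: d + half - min_dist]
        v[d - min_dist] = seg.var(ddof=1)
    interior = slice(left_anchor - min_dist, right_anchor - min_dist + 1)
    v[: left_anchor - min_dist] = v[left_anchor - min_dist]
    v[right_anchor - min_dist + 1:] = np.nanmax(v[interior])

    v = np.maximum(v, max(np.nanmax(v) * 1e-12, 1e-30))
    w = (1.0 / v) ** 0.25
    dup = np.floor(w / w.min()).astype(np.int64)
    dup = np.minimum(dup, max_dup)
    dup[~defined] = 0  # interpolated gap distances carry no weight
    if dup.sum() == 0:
        dup = np.ones(n, dtype=np.int64)
    frac = lowess_frac
    if frac is None:
        frac = 15.0 / (dup.max() * w.mean())
    # a local window must span more than one distinct distance or the tricube
    # weights degenerate on the duplicated points
    min_frac = min(1.0, (2.0 * dup.max() + 1.0) / dup.sum())
    frac = float(np.clip(frac, min_frac, 1.0))
    xs = np.repeat(dists, dup).astype(float)
    ys = np.repeat(filled, dup)
    g = sm.nonparametric.lowess(ys, xs, frac=frac, it=0, xvals=dists.astype(float))
    bad = ~np.isfinite(g)
    if bad.any():
        g[bad] = filled[bad]

    increasing = np.flatnonzero(np.diff(filled) > 0)
    d_star = int(dists[increasing[0] + 1]) if increasing.size else min_dist
    final = np.where(dists < d_star, filled, g)
    final = np.maximum(final, ALPHA_BOUNDS[0])
    return DispersionCurve(min_dist, max_dist, alpha_raw, filled, v, w, dup,
                           g, d_star, final, frac)


def estimate_ddr(counts: dict, scaling: dict, tested: np.ndarray,
                 design: StudyDesign, lowess_frac: float | None = None,
                 max_pixels_per_distance: int | None = None,
                 rng: np.random.Generator | None = None) -> DispersionModel:
    """Estimate and smooth the DDR for every condition.

    ``counts``/``scaling`` map replicate -> banded arrays.  Estimation pools
    all tested pixels at each distance (optionally subsampled to
    ``max_pixels_per_distance`` for large matrices).  Neighbouring distances
    warm-start each other's qCML iteration.
    """
    lo, hi = design.min_dist_bins, design.max_dist_bins
    curves = {}
    for c in design.conditions:
        reps = design.replicates_of(c)
        if len(reps) < 2:
            raise ValueError(f"dispersion estimation needs >= 2 replicates "
                             f"in condition {c!r}")
        xs = np.stack([counts[r] for r in reps], axis=-1)
        ks = np.stack([scaling[r] for r in reps], axis=-1)
        raw = np.full(hi - lo + 1, np.nan)
        warm = 0.01
        for d in range(lo, hi + 1):
            rows = np.flatnonzero(tested[:, d])
            if rows.size == 0:
                continue
            if (max_pixels_per_distance is not None
                    and rows.size > max_pixels_per_distance):
                sel = (rng or np.random.default_rng(0)).choice(
                    rows.size, max_pixels_per_distance, replace=False)
                rows = rows[np.sort(sel)]
            a = qcml_dispersion(xs[rows, d, :], ks[rows, d, :], alpha0=warm)
            raw[d - lo] = a
            warm = a
        curves[c] = smooth_ddr(raw, lo, hi, lowess_frac=lowess_frac)
    return DispersionModel(curves)


def global_dispersion(counts: dict, scaling: dict, pixel_mask: np.ndarray,
                      design: StudyDesign) -> dict:
    """Single qCML dispersion per condition pooling all masked pixels,
    irrespective of distance (the 'global NB' alternative model)."""
    out = {}
    ii, dd = np.nonzero(pixel_mask)
    for c in design.conditions:
        reps = design.replicates_of(c)
        x = np.stack([counts[r][ii, dd] for r in reps], axis=1)
        k = np.stack([scaling[r][ii, dd] for r in reps], axis=1)
        out[c] = qcml_dispersion(x, k)
    return out
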