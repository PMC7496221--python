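"""Locus-specific bias vectors and distance-dependent size factors.

The count model is multiplicative: ``x[r,i,j] ~ mu * b[r,i] * b[r,j] * s[r,j-i]``.
Bias vectors come from matrix balancing (equal scaled row sums); size factors
are a distance-dependent median-of-ratios against the across-replicate
geometric mean, interpolated piecewise-linearly between distance-group anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StudyDesign, banded_valid_mask

__all__ = ["kr_balance", "NormalizationModel", "estimate_size_factors", "normalize"]


class BalanceError(RuntimeError):
    pass


def kr_balance(matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 3000,
               bias_bounds: tuple = (0.1, 10.0)):
    """Balance a symmetric non-negative matrix; return the per-bin bias vector.

    Finds ``b > 0`` such that the matrix scaled by ``1 / (b_i b_j)`` has equal
    row sums, via a damped multiplicative fixed-point iteration on the
    Knight-Ruiz balancing condition ``x * (A x) = const`` (``b = 1/x`` up to
    scale).  The returned bias vector is rescaled so that the mean over
    retained bins is 1; bins whose bias falls outside ``bias_bounds`` after
    rescaling are set to NaN (excluded), as are all-zero rows.

    Raises
    ------
    BalanceError
        If the iteration does not converge; usually a sign that sparse rows
        should be filtered more aggressively first.
    """
    A = np.asarray(matrix, dtype=float)
    n = A.shape[0]
    rowsum = A.sum(axis=1)
    active = rowsum > 0
    if not active.any():
        return np.full(n, np.nan)
    Aa = A[np.ix_(active, active)]
    x = 1.0 / np.sqrt(Aa.sum(axis=1))
    converged = False
    for _ in range(max_iter):
        ax = Aa @ x
        r = x * ax  # scaled row sums
        mean_r = r.mean()
        if np.std(r) / mean_r <= tol:
            converged = True
            break
        # geometric-mean damping of the Sinkhorn update x <- 1 / (A x)
        x = np.sqrt(x * mean_r / ax)
    if not converged:
        raise BalanceError(
            "matrix balancing did not converge; filter sparse rows more "
            "aggressively before balancing")
    bias_active = 1.0 / x
    lo, hi = bias_bounds
    # robust pre-pass on the median scale (a single extreme bin would skew a
    # mean-based cut), then the stated cut on the mean-1 scale of what is left
    med = np.median(bias_active)
    rel = bias_active / med
    bias_active[(rel < lo) | (rel > hi)] = np.nan
    ok = np.isfinite(bias_active)
    if ok.any():
        bias_active = bias_active / bias_active[ok].mean()
        bias_active[(bias_active < lo) | (bias_active > hi)] = np.nan
        ok = np.isfinite(bias_active)
        if ok.any():
            bias_active = bias_active / bias_active[ok].mean()
    bias = np.full(n, np.nan)
    bias[active] = bias_active
    return bias


@dataclass
class NormalizationModel:
    """Per-replicate bias vectors and per-distance size factors.

    Attributes
    ----------
    bias:
        dict replicate -> array of shape (n_bins,), NaN for excluded bins.
    size_factors:
        dict replicate -> array of shape (max_dist + 1,), strictly positive;
        piecewise linear between group anchors, constant beyond them.
    group_factors, group_mean_distances:
        The raw per-group medians-of-ratios and group anchor distances.
    zero_excluded:
        Banded boolean mask of pixels with a zero count in any replicate;
        these are excluded from all further analysis.
    """

    bias: dict
    size_factors: dict
    group_factors: dict
    group_mean_distances: np.ndarray
    zero_excluded: np.ndarray

    def save(self, bias_path, size_factor_path):
        """Serialize bias vectors (replicate, bin, bias) and size factors
        (replicate, distance, factor) as TSV."""
        with open(bias_path, "w") as fh:
            fh.write("replicate\tbin\tbias\n")
            for r, b in self.bias.items():
                for i, v in enumerate(b):
                    fh.write(f"{r}\t{i}\t{v:.12g}\n")
        with open(size_factor_path, "w") as fh:
            fh.write("replicate\tdistance\tsize_factor\n")
            for r, s in self.size_factors.items():
                for d, v in enumerate(s):
                    fh.write(f"{r}\t{d}\t{v:.12g}\n")


def estimate_size_factors(counts: dict, bias: dict, design: StudyDesign,
                          n_groups: int = 100) -> NormalizationModel:
    """Distance-dependent median-of-ratios size factors.

    Parameters
    ----------
    counts:
        dict replicate -> banded count array ``(n_bins, max_dist + 1)``.
    bias:
        dict replicate -> bias vector (NaN = excluded bin).

    Pixels eligible for pooling have distance within the banded range, all
    touched bins retained in every replicate, and a nonzero count in every
    replicate (so the geometric-mean denominator is well defined).  They are
    grouped into ``n_groups`` equal-count groups by distance; each group's
    factor is the median of balanced-count ratios to the across-replicate
    geometric mean.
    """
    reps = design.replicates
    first = counts[reps[0]]
    n_bins, width = first.shape
    max_dist = width - 1
    valid = banded_valid_mask(n_bins, max_dist)

    # balanced counts y = x / (b_i b_j); NaN propagates bin exclusions
    y = {}
    for r in reps:
        b = bias[r]
        scale = b[:, None] * _shifted_bias(b, max_dist)
        y[r] = counts[r] / scale

    stack = np.stack([y[r] for r in reps])  # (R, n_bins, D+1)
    xstack = np.stack([counts[r] for r in reps])
    all_pos = np.isfinite(stack).all(axis=0) & (np.nan_to_num(xstack) > 0).all(axis=0)
    zero_excluded = valid & ~(np.nan_to_num(xstack) > 0).all(axis=0)
    dgrid = np.broadcast_to(np.arange(width)[None, :], (n_bins, width))
    eligible = all_pos & valid & (dgrid >= 1)

    ii, dd = np.nonzero(eligible)
    if ii.size < n_groups:
        raise ValueError(
            f"only {ii.size} eligible pixels for {n_groups} distance groups; "
            "reduce n_groups")
    logy = np.log(stack[:, ii, dd])  # (R, n_pix)
    ratios = np.exp(logy - logy.mean(axis=0, keepdims=True))

    order = np.argsort(dd, kind="stable")
    groups = np.array_split(order, n_groups)
    anchors = np.empty(n_groups)
    gf = {r: np.empty(n_groups) for r in reps}
    for k, g in enumerate(groups):
        if g.size == 0:
            raise ValueError("empty distance group; reduce n_groups")
        anchors[k] = dd[g].mean()
        for ri, r in enumerate(reps):
            gf[r][k] = np.median(ratios[ri, g])

    size_factors = {}
    d_all = np.arange(width, dtype=float)
    for r in reps:
        size_factors[r] = np.interp(d_all, anchors, gf[r])  # clamps at the ends
    return NormalizationModel(bias=dict(bias), size_factors=size_factors,
                              group_factors=gf, group_mean_distances=anchors,
                              zero_excluded=zero_excluded)


def _shifted_bias(b: np.ndarray, max_dist: int) -> np.ndarray:
    """Matrix S[i, d] = b[i + d] (NaN beyond the edge)."""
    n = b.shape[0]
    out = np.full((n, max_dist + 1), np.nan)
    for d in range(max_dist + 1):
        out[: n - d, d] = b[d:]
    return out


def combined_scaling(model: NormalizationModel, replicate, n_bins, max_dist):
    """Banded combined scaling factor k[r,i,d] = b_i * b_{i+d} * s_{r,d}."""
    b = model.bias[replicate]
    return b[:, None] * _shifted_bias(b, max_dist) * model.size_factors[replicate][None, :]


def normalize(counts: dict, model: NormalizationModel, design: StudyDesign) -> dict:
    """Normalized counts z = x / (b_i b_j s_{j-i}); NaN at excluded pixels."""
    out = {}
    for r in design.replicates:
        n_bins, width = counts[r].shape
        out[r] = counts[r] / combined_scaling(model, r, n_bins, width - 1)
    return out
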