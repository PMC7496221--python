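"""End-to-end Hi-C differential loop calling.

Order of operations: sparse-row filtering, matrix balancing, distance-dependent
size factors, normalized condition means and the tested-pixel mask, dispersion
estimation (pooled DDR by default, with Poisson / global-NB / sample-variance
alternatives), the per-pixel NB likelihood-ratio test restricted to the loop
footprint, BH-FDR across all loop pixels, spatial clustering of significant
and insignificant pixels, and condition classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ContactMatrix, Loop, LoopList, StudyDesign
from .dispersion import (DispersionModel, condition_means, estimate_ddr,
                         global_dispersion, tested_mask)
from .nbtest import (bh_fdr, classify_pixels, cluster_pixels, lrt_pixels,
                     sample_variance_alpha)
from .normalization import (NormalizationModel, combined_scaling,
                            estimate_size_factors, kr_balance, normalize)

__all__ = ["run_hic_pipeline", "HicPipelineResult", "sparse_row_exclusions"]

DISPERSION_MODES = ("pooled", "poisson", "global", "sample-variance")


def sparse_row_exclusions(band: np.ndarray, min_nonzero: int = 25,
                          window: int = 300) -> np.ndarray:
    """Bins with fewer than ``min_nonzero`` nonzero entries at offsets
    1..``window`` from the diagonal (both directions), on a banded matrix."""
    n_bins, width = band.shape
    nz = np.zeros(n_bins, dtype=np.int64)
    x = np.nan_to_num(band) > 0
    for d in range(1, min(window, width - 1) + 1):
        col = x[: n_bins - d, d]
        nz[: n_bins - d] += col
        nz[d:] += col
    return nz < min_nonzero


def _banded_to_dense(band: np.ndarray) -> np.ndarray:
    n_bins, width = band.shape
    dense = np.zeros((n_bins, n_bins))
    for d in range(width):
        v = np.nan_to_num(band[: n_bins - d, d])
        idx = np.arange(n_bins - d)
        dense[idx, idx + d] = v
        dense[idx + d, idx] = v
    return dense


@dataclass
class HicPipelineResult:
    table: pd.DataFrame
    clusters: LoopList
    norm: NormalizationModel
    dispersion: DispersionModel | None
    tested: np.ndarray
    design: StudyDesign
    excluded_bins: np.ndarray


def run_hic_pipeline(counts: dict, design: StudyDesign, loops: LoopList,
                     chrom: str | None = None, fdr: float = 0.01,
                     min_cluster_size: int = 3,
                     dispersion_mode: str = "pooled",
                     lowess_frac: float | None = None,
                     sparse_filter: bool = True,
                     truth: np.ndarray | None = None,
                     max_pixels_per_distance: int | None = None,
                     seed: int | None = None) -> HicPipelineResult:
    """Run the full differential pipeline on one chromosome.

    ``counts`` maps replicate id to either a ContactMatrix or a banded array.
    ``truth`` (optional, banded 0/1 from a simulation) is carried into the
    result table for evaluation.
    """
    if dispersion_mode not in DISPERSION_MODES:
        raise ValueError(f"unknown dispersion mode {dispersion_mode!r}")
    max_dist = design.max_dist_bins
    band = {}
    for r in design.replicates:
        m = counts[r]
        if isinstance(m, ContactMatrix):
            band[r] = m.to_banded(max_dist)
            if chrom is None:
                chrom = m.chrom
        else:
            band[r] = np.asarray(m, dtype=float)
    if chrom is None:
        chrom = "chrS"
    n_bins = band[design.replicates[0]].shape[0]

    excluded = np.zeros(n_bins, dtype=bool)
    if sparse_filter:
        for r in design.replicates:
            excluded |= sparse_row_exclusions(band[r], window=min(300, max_dist))

    bias = {}
    for r in design.replicates:
        dense = _banded_to_dense(band[r])
        dense[excluded, :] = 0.0
        dense[:, excluded] = 0.0
        bias[r] = kr_balance(dense)

    norm = estimate_size_factors(band, bias, design)
    z = normalize(band, norm, design)
    zbar = condition_means(z, design)
    tested = tested_mask(zbar, design, zero_excluded=norm.zero_excluded)
    scaling = {r: combined_scaling(norm, r, n_bins, max_dist)
               for r in design.replicates}

    # loop footprint restricted to the tested distance range
    loop_pix = sorted(
        (i, j) for (i, j) in loops.union_pixels(chrom)
        if design.min_dist_bins <= j - i <= design.max_dist_bins and j < n_bins)
    ii = np.array([p[0] for p in loop_pix], dtype=np.int64)
    dd = np.array([p[1] - p[0] for p in loop_pix], dtype=np.int64)
    is_tested = tested[ii, dd] if loop_pix else np.zeros(0, dtype=bool)
    ti, td = ii[is_tested], dd[is_tested]

    conditions = design.conditions
    reps = design.replicates
    cond_index = np.array([conditions.index(design.condition_of[r])
                           for r in reps])
    x = np.stack([band[r][ti, td] for r in reps], axis=1)
    k = np.stack([scaling[r][ti, td] for r in reps], axis=1)

    disp_model = None
    if dispersion_mode == "pooled":
        disp_model = estimate_ddr(band, scaling, tested, design,
                                  lowess_frac=lowess_frac,
                                  max_pixels_per_distance=max_pixels_per_distance,
                                  rng=np.random.default_rng(seed))
        alpha = np.stack([disp_model.alpha_at(conditions[cond_index[col]], td)
                          for col in range(len(reps))], axis=1)
    elif dispersion_mode == "poisson":
        alpha = np.zeros_like(x)
    elif dispersion_mode == "global":
        loop_mask = np.zeros_like(tested)
        loop_mask[ti, td] = True
        g = global_dispersion(band, scaling, loop_mask, design)
        alpha = np.stack([np.full(len(ti), g[conditions[cond_index[col]]])
                          for col in range(len(reps))], axis=1)
    else:  # sample-variance
        alpha = np.empty_like(x)
        for ci, c in enumerate(conditions):
            creps = design.replicates_of(c)
            if len(creps) < 2:
                raise ValueError("sample-variance dispersion needs >= 2 "
                                 f"replicates in condition {c!r}")
            zc = np.stack([z[r][ti, td] for r in creps], axis=1)
            a = sample_variance_alpha(zc.mean(axis=1), zc.var(axis=1, ddof=1))
            for col in np.flatnonzero(cond_index == ci):
                alpha[:, col] = a

    stat, p, mu0, mu_alt = lrt_pixels(x, k, alpha, cond_index, len(conditions))
    q = bh_fdr(p)

    sig = [(int(i), int(i + d)) for i, d, qq in zip(ti, td, q) if qq <= fdr]
    insig = [(int(i), int(i + d)) for i, d, qq in zip(ti, td, q) if qq > fdr]
    sig_clusters, _ = cluster_pixels(sig, min_cluster_size)
    insig_clusters, _ = cluster_pixels(insig, min_cluster_size)

    zbar_at = {c: zbar[c][ti, td] for c in conditions}
    pix_index = {(int(i), int(i + d)): n for n, (i, d) in enumerate(zip(ti, td))}
    labels = {}
    cluster_ids = {}
    means_of = {pix: [zbar_at[c][pix_index[pix]] for c in conditions]
                for cl in sig_clusters for pix in cl}
    cls_labels, _tie = classify_pixels(means_of, conditions)
    for cid, cl in enumerate(sig_clusters):
        for pix in cl:
            labels[pix] = cls_labels[pix]
            cluster_ids[pix] = f"diff_{cid}"
    for cid, cl in enumerate(insig_clusters):
        for pix in cl:
            labels[pix] = "constitutive"
            cluster_ids[pix] = f"const_{cid}"

    rows = []
    for n_, (i, d) in enumerate(zip(ti, td)):
        pix = (int(i), int(i + d))
        row = {"chrom": chrom, "i": pix[0], "j": pix[1], "d": int(d),
               "distance_bp": int(d) * design.bin_size, "tested": True}
        for c in conditions:
            row[f"zbar_{c}"] = zbar_at[c][n_]
        row["mu_null"] = mu0[n_]
        for ci, c in enumerate(conditions):
            row[f"mu_{c}"] = mu_alt[n_, ci]
        row.update(lrt_stat=stat[n_], p=p[n_], q=q[n_],
                   label=labels.get(pix, "unclassified"),
                   cluster_id=cluster_ids.get(pix, ""))
        if truth is not None:
            row["truth"] = int(truth[pix[0], d])
        rows.append(row)
    for i, d in zip(ii[~is_tested], dd[~is_tested]):
        row = {"chrom": chrom, "i": int(i), "j": int(i + d), "d": int(d),
               "distance_bp": int(d) * design.bin_size, "tested": False,
               "label": "untested", "cluster_id": ""}
        if truth is not None:
            row["truth"] = int(truth[i, d])
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["i", "j"], kind="stable").reset_index(drop=True)

    cluster_loops = []
    for cid, cl in enumerate(sig_clusters):
        lab = labels[next(iter(cl))]
        # modal pixel label for the cluster record
        labs = [labels[p_] for p_ in cl]
        lab = max(set(labs), key=labs.count)
        cluster_loops.append(Loop(chrom, frozenset(cl), f"diff_{cid}",
                                  category=lab))
    for cid, cl in enumerate(insig_clusters):
        cluster_loops.append(Loop(chrom, frozenset(cl), f"const_{cid}",
                                  category="constitutive"))
    return HicPipelineResult(table, LoopList(cluster_loops), norm, disp_model,
                             tested, design, np.flatnonzero(excluded))
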