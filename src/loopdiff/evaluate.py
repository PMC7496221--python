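"""Scoring of differential calls against simulation truth.

The score for a loop pixel is 1 - q; performance is summarized by ROC/AUROC,
observed-FDR and power curves over nominal FDR thresholds, distance-stratified
versions of the same (with BH re-run within each stratum), and the low-p
distance-bias proportions on null simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc, roc_curve

from .nbtest import bh_fdr

__all__ = ["roc_auroc", "fdr_control_curve", "power_curve", "assign_strata",
           "distance_stratified_eval", "low_p_distance_bias"]

STRATA_BOUNDS_BP = (400_000, 800_000)  # [0,400k), [400k,800k), [800k,inf)
STRATA = ("short", "medium", "long")


def roc_auroc(score, truth):
    """ROC curve over all thresholds and its trapezoid-rule area."""
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ValueError("both truth classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(truth, np.asarray(score, dtype=float))
    return (fpr, tpr), float(auc(fpr, tpr))


def fdr_control_curve(q, truth, thresholds):
    """Observed FDR = FP / (FP + TP) among pixels called at q <= threshold;
    0 by convention when nothing is called."""
    q = np.asarray(q, dtype=float)
    truth = np.asarray(truth).astype(bool)
    out = np.zeros(len(thresholds))
    for i, thr in enumerate(thresholds):
        called = q <= thr
        n = called.sum()
        out[i] = 0.0 if n == 0 else float((~truth[called]).sum() / n)
    return out


def power_curve(q, truth, thresholds):
    """True-positive rate among truly differential pixels at each q threshold."""
    q = np.asarray(q, dtype=float)
    truth = np.asarray(truth).astype(bool)
    npos = truth.sum()
    if npos == 0:
        raise ValueError("power is undefined without true positives")
    return np.array([float((q[truth] <= thr).sum() / npos)
                     for thr in thresholds])


def assign_strata(distance_bp):
    """Stratum label per anchor distance (left-closed/right-open bounds)."""
    d = np.asarray(distance_bp, dtype=float)
    lo, hi = STRATA_BOUNDS_BP
    out = np.where(d < lo, "short", np.where(d < hi, "medium", "long"))
    return out.astype(object)


@dataclass
class StratumReport:
    stratum: str
    n: int
    q: np.ndarray
    fdr_curve: np.ndarray | None
    power: np.ndarray | None
    auroc: float | None


def distance_stratified_eval(p, truth, distance_bp, thresholds) -> dict:
    """Re-run BH within each distance stratum, then FDR/power/ROC per stratum.

    Empty strata are omitted.  Within-stratum q-values are not comparable to
    the global ones (BH on a subset can move either way).
    """
    strata = assign_strata(distance_bp)
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth).astype(bool)
    reports = {}
    for s in STRATA:
        sel = strata == s
        if not sel.any():
            continue
        qs = bh_fdr(p[sel])
        ts = truth[sel]
        fdrc = fdr_control_curve(qs, ts, thresholds)
        pw = power_curve(qs, ts, thresholds) if ts.any() else None
        try:
            _, a = roc_auroc(1.0 - qs, ts)
        except ValueError:
            a = None
        reports[s] = StratumReport(s, int(sel.sum()), qs, fdrc, pw, a)
    return reports


def low_p_distance_bias(p, distance_bp, percentile: float = 5.0) -> dict:
    """Proportion of loop pixels per stratum with p below the global
    ``percentile``-th percentile of all loop-pixel p-values.  An unbiased
    model on a null simulation gives ~percentile/100 in every stratum."""
    p = np.asarray(p, dtype=float)
    cut = np.percentile(p, percentile)
    strata = assign_strata(distance_bp)
    out = {}
    for s in STRATA:
        sel = strata == s
        if sel.any():
            out[s] = float((p[sel] < cut).mean())
    return out
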