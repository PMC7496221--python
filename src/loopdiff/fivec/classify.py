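"""Interaction-score thresholding into looping classes with empirical FDR.

Pixels whose scores are low in every replicate are background; a pixel is a
candidate loop when all replicates of at least one condition clear the
significance threshold g.  Candidates are assigned to differential classes
(every nonempty proper subset of the condition set) by requiring the minimum
across-replicate IS difference against each outside condition to reach a
difference threshold d.  The per-class d is chosen by sweeping d and
comparing call counts on the experimental set against call counts on
simulated same-condition null replicate sets (empirical FDR), keeping the d
whose eFDR is closest to the target while remaining below it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..nbtest import cluster_pixels

__all__ = ["ClassifyConfig", "differential_classes", "background_filter",
           "significance_filter", "difference_classify", "efdr_map", "EFDRMap",
           "cluster_classified"]


def _is10(p):
    return -10.0 * np.log2(p)


@dataclass
class ClassifyConfig:
    background_threshold: float = _is10(0.8)     # b
    significance_threshold: float = _is10(0.165)  # g
    tau: float = 0.02
    sweep: np.ndarray = field(
        default_factory=lambda: np.arange(0.5, 40.0 + 1e-9, 0.5))
    n_null_sets: int = 1
    min_cluster_size: int = 3

    def __post_init__(self):
        if not self.background_threshold < self.significance_threshold:
            raise ValueError("background threshold must be below the "
                             "significance threshold")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        d = np.asarray(self.sweep, dtype=float)
        if d.size == 0 or (d <= 0).any() or (np.diff(d) <= 0).any():
            raise ValueError("sweep grid must be strictly increasing and "
                             "positive")


def differential_classes(conditions) -> list:
    """All nonempty proper subsets of the condition set, singles first."""
    conditions = list(conditions)
    if len(conditions) not in (2, 3):
        raise ValueError("classification supports 2 or 3 conditions")
    classes = [frozenset([c]) for c in conditions]
    if len(conditions) == 3:
        classes += [frozenset([a, b]) for i, a in enumerate(conditions)
                    for b in conditions[i + 1:]]
    return classes


def _stack_stats(is_stack: dict, conditions):
    """Per-condition min/max over replicates plus the overall finite mask."""
    mins, maxs = {}, {}
    finite = None
    for t in conditions:
        arr = np.asarray(is_stack[t], dtype=float)
        f = np.isfinite(arr).all(axis=0)
        finite = f if finite is None else (finite & f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mins[t] = np.min(arr, axis=0)
            maxs[t] = np.max(arr, axis=0)
    return mins, maxs, finite


def background_filter(is_stack: dict, conditions, b: float):
    """Background pixels: max IS over all replicates of all conditions < b."""
    if not conditions:
        raise ValueError("empty condition set")
    _mins, maxs, finite = _stack_stats(is_stack, conditions)
    overall = np.max(np.stack([maxs[t] for t in conditions]), axis=0)
    return finite & (overall < b)


def significance_filter(is_stack: dict, conditions, g: float):
    """Candidate loops: in at least one condition, every replicate exceeds g."""
    mins, _maxs, finite = _stack_stats(is_stack, conditions)
    best = np.max(np.stack([mins[t] for t in conditions]), axis=0)
    return finite & (best > g)


def difference_classify(is_stack: dict, conditions, d: float, g: float):
    """Preliminary class masks at difference threshold d.

    Delta[t, u] = min over replicate pairs of (IS in t - IS in u)
                = min_s IS_t - max_s IS_u.
    Single class {t}: Delta[t, u] >= d against both other conditions and t
    passes significance.  Dual class {t, t'}: both beat the remaining
    condition by >= d, both pass significance, and neither of the pair beats
    the other by >= d.  Constitutive: all conditions significant and no
    ordered Delta reaches d.  Remaining candidates are 'other'.
    """
    conditions = list(conditions)
    mins, maxs, finite = _stack_stats(is_stack, conditions)
    candidate = significance_filter(is_stack, conditions, g)
    delta = {(t, u): mins[t] - maxs[u]
             for t in conditions for u in conditions if t != u}
    passes = {t: mins[t] > g for t in conditions}
    masks = {}
    assigned = np.zeros_like(candidate)
    for cls in differential_classes(conditions):
        inside = sorted(cls, key=conditions.index)
        outside = [u for u in conditions if u not in cls]
        m = candidate.copy()
        for t in inside:
            m &= passes[t]
            for u in outside:
                m &= delta[(t, u)] >= d
        if len(inside) == 2:
            t, t2 = inside
            m &= (delta[(t, t2)] < d) & (delta[(t2, t)] < d)
        m &= ~assigned
        masks[cls] = m & finite
        assigned |= masks[cls]
    const = candidate & ~assigned & finite
    for t in conditions:
        const &= passes[t]
    for key, dl in delta.items():
        const &= dl < d
    masks["constitutive"] = const
    masks["other"] = candidate & finite & ~assigned & ~const
    return masks


def _upper(mask):
    return np.triu(mask, k=1)


def _count_calls(region_stacks: dict, conditions, d, g, classes):
    counts = dict.fromkeys(classes, 0)
    for region, is_stack in region_stacks.items():
        masks = difference_classify(is_stack, conditions, d, g)
        for cls in classes:
            counts[cls] += int(_upper(masks[cls]).sum())
    return counts


@dataclass
class EFDRMap:
    """Difference-threshold -> eFDR mapping per class, with selections."""

    sweep: np.ndarray
    n_exp: dict       # class -> array over sweep
    n_null: dict      # class -> mean over null sets
    efdr: dict        # class -> array over sweep
    selected: dict    # class -> chosen d (or None)
    final_masks: dict  # class -> {region: bool matrix}
    labels: dict      # region -> object matrix of final class labels


def select_threshold(sweep, efdr_values, tau):
    """The d whose eFDR is closest to tau while remaining strictly below it;
    ties break toward the smaller d (more calls).  None when no d qualifies."""
    sweep = np.asarray(sweep, dtype=float)
    efdr_values = np.asarray(efdr_values, dtype=float)
    ok = efdr_values < tau
    if not ok.any():
        return None
    gap = tau - efdr_values[ok]
    best = np.flatnonzero(ok)[np.argmin(gap)]
    return float(sweep[best])


def efdr_map(exp_stacks: dict, null_stack_sets: list, conditions,
             config: ClassifyConfig) -> EFDRMap:
    """Sweep difference thresholds, estimate per-class eFDR against the null
    replicate sets, select per-class thresholds, and produce final labels.

    ``exp_stacks``: region -> {condition: (n_reps, m, m) IS array}.
    ``null_stack_sets``: list of structures shaped like ``exp_stacks`` built
    from same-condition simulated replicates relabeled as the conditions.
    eFDR is 0 by convention when the experimental set has no calls.
    """
    classes = differential_classes(conditions)
    sweep = np.asarray(config.sweep, dtype=float)
    g = config.significance_threshold
    n_exp = {cls: np.zeros(len(sweep)) for cls in classes}
    n_null = {cls: np.zeros(len(sweep)) for cls in classes}
    for di, d in enumerate(sweep):
        ce = _count_calls(exp_stacks, conditions, d, g, classes)
        for cls in classes:
            n_exp[cls][di] = ce[cls]
        for null_stacks in null_stack_sets:
            cn = _count_calls(null_stacks, conditions, d, g, classes)
            for cls in classes:
                n_null[cls][di] += cn[cls]
    efdr = {}
    for cls in classes:
        n_null[cls] /= max(len(null_stack_sets), 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            e = n_null[cls] / n_exp[cls]
        e[n_exp[cls] == 0] = 0.0
        efdr[cls] = e
    selected = {cls: select_threshold(sweep, efdr[cls], config.tau)
                for cls in classes}
    final_masks = {cls: {} for cls in classes}
    labels = {}
    for region, is_stack in exp_stacks.items():
        shape = np.asarray(is_stack[conditions[0]]).shape[1:]
        lab = np.full(shape, "", dtype=object)
        taken = np.zeros(shape, dtype=bool)
        for cls in classes:
            if selected[cls] is None:
                warnings.warn(f"class {set(cls)} has no threshold with "
                              f"eFDR < {config.tau}; returning no calls")
                final_masks[cls][region] = np.zeros(shape, dtype=bool)
                continue
            masks = difference_classify(is_stack, conditions,
                                        selected[cls], g)
            m = _upper(masks[cls]) & ~taken
            final_masks[cls][region] = m
            taken |= m
            lab[m] = "+".join(sorted(cls, key=list(conditions).index))
        labels[region] = lab
    return EFDRMap(sweep, n_exp, n_null, efdr, selected, final_masks, labels)


def cluster_classified(final_masks: dict, min_size: int = 3) -> dict:
    """4-connected clusters within each class per region; undersized clusters
    are dropped to 'unclassified'."""
    out = {}
    for cls, regions in final_masks.items():
        out[cls] = {}
        for region, mask in regions.items():
            pix = list(zip(*np.nonzero(_upper(mask))))
            clusters, _discarded = cluster_pixels(pix, min_size)
            out[cls][region] = clusters
    return out
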