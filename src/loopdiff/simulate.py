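"""Simulation of raw Hi-C contact matrices with known differential-loop truth.

A fully synthetic baseline (power-law distance decay with planted focal
loops) stands in for a real condition's normalized mean field.  Loops are
labelled constitutive or truly differential (four equal-probability
categories: up/down in each of two artificial conditions), loop pixels are
perturbed by the effect size and their non-loop neighbours by half of it,
replicate-level biases and distance-dependent depth factors are re-imposed,
and raw counts are drawn from NB(mu_biased, alpha(d)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Loop, LoopList, StudyDesign, banded_valid_mask
from .nb import nb_rvs

__all__ = ["SyntheticBaseline", "make_synthetic_baseline", "default_dispersion",
           "label_and_perturb", "bias_and_sample", "simulate_dataset",
           "estimate_truth_prevalence", "SimulatedDataset"]

CATEGORIES = ("constitutive", "up_A", "down_A", "up_B", "down_B")


@dataclass
class SyntheticBaseline:
    zbar: np.ndarray          # banded normalized mean field
    loops: LoopList
    n_bins: int
    bin_size: int
    min_dist: int
    max_dist: int
    chrom: str = "chrS"


def make_synthetic_baseline(n_bins: int = 2000, n_loops: int = 200,
                            gamma: float = 1.0, enrichment: float = 4.0,
                            mean_at_max: float = 8.0, min_dist: int = 4,
                            max_dist: int = 500, loop_size: int = 2,
                            bin_size: int = 10_000, seed=None,
                            chrom: str = "chrS",
                            max_attempts: int = 10_000) -> SyntheticBaseline:
    """Power-law decay mean field with non-overlapping planted loop foci.

    The field is ``scale * d^-gamma`` with ``scale`` chosen so the mean at the
    maximum tested distance equals ``mean_at_max``; each loop is a
    ``loop_size x loop_size`` block of pixels multiplied by ``enrichment``.
    Loop centres are uniform in distance over the tested range, and loops are
    redrawn if they would come within 2 pixels (Chebyshev) of an existing one
    so that perturbation halos never overlap other loops.  Deterministic
    given ``seed``.
    """
    if min(n_bins, gamma, enrichment, mean_at_max, loop_size, bin_size) <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    scale = mean_at_max * max_dist ** gamma
    d = np.arange(max_dist + 1, dtype=float)
    decay = scale * np.maximum(d, 1.0) ** (-gamma)
    zbar = np.tile(decay, (n_bins, 1))
    zbar[~banded_valid_mask(n_bins, max_dist)] = np.nan

    loops = []
    occupied = set()
    attempts = 0
    margin = 2
    while len(loops) < n_loops:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("could not place non-overlapping loops; "
                               "reduce n_loops or enlarge the matrix")
        dc = int(rng.integers(min_dist + loop_size, max_dist - loop_size + 1))
        i0 = int(rng.integers(0, n_bins - dc - loop_size))
        block = [(i0 + a, i0 + dc + b)
                 for a in range(loop_size) for b in range(loop_size)]
        clash = any((pi + di, pj + dj) in occupied
                    for (pi, pj) in block
                    for di in range(-margin, margin + 1)
                    for dj in range(-margin, margin + 1))
        if clash:
            continue
        occupied.update(block)
        loops.append(Loop(chrom, frozenset(block), f"loop_{len(loops)}"))
        for (i, j) in block:
            zbar[i, j - i] *= enrichment
    return SyntheticBaseline(zbar, LoopList(loops), n_bins, bin_size,
                             min_dist, max_dist, chrom)


def default_dispersion(d):
    """Default simulated DDR: sharp decrease at very short range, then a slow
    rise with distance (the shape seen in deep Hi-C data)."""
    d = np.asarray(d, dtype=float)
    return 0.03 + 0.10 * np.exp(-d / 3.0) + 0.0003 * d


@dataclass
class PerturbedField:
    mu: dict                      # condition -> banded mean field
    truth: np.ndarray             # banded 0/1 truth labels (loop pixels only)
    categories: dict              # loop_id -> category


def label_and_perturb(baseline: SyntheticBaseline, beta: float, p_diff: float,
                      rng, conditions=("A", "B")) -> PerturbedField:
    """Assign loop categories and build per-condition true mean fields.

    Truly differential loops (probability ``p_diff``, split equally among
    up/down in each condition) have their member pixels scaled by
    ``1 +- beta`` in the matching condition; non-loop 4-neighbours of
    perturbed loop pixels get half the effect.  Truth is 1 exactly on the
    member pixels of truly differential loops.
    """
    if not 0 <= p_diff <= 1:
        raise ValueError("p_diff must lie in [0, 1]")
    if beta < 0:
        raise ValueError("effect size must be non-negative")
    if beta > 1:
        raise ValueError("effect size > 1 would drive down-perturbed means "
                         "negative")
    ca, cb = conditions
    probs = [1 - p_diff] + [p_diff / 4] * 4
    cats = rng.choice(len(CATEGORIES), size=len(baseline.loops), p=probs)
    mu = {ca: baseline.zbar.copy(), cb: baseline.zbar.copy()}
    truth = np.zeros_like(baseline.zbar, dtype=np.int8)
    categories = {}
    loop_union = baseline.loops.union_pixels()
    halos = {(c, s): set() for c in (ca, cb) for s in (+1, -1)}
    for lp, ci in zip(baseline.loops, cats):
        cat = CATEGORIES[ci]
        categories[lp.loop_id] = cat
        lp.category = cat
        if cat == "constitutive":
            continue
        cond = ca if cat.endswith("_A") else cb
        sign = +1 if cat.startswith("up") else -1
        factor = 1.0 + sign * beta
        for (i, j) in lp.pixels:
            mu[cond][i, j - i] *= factor
            truth[i, j - i] = 1
            for (ni, nj) in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                if (ni, nj) not in loop_union and 0 <= ni <= nj:
                    halos[(cond, sign)].add((ni, nj))
    for (cond, sign), pix in halos.items():
        if sign == -1:  # an up-halo from another loop takes precedence
            pix = pix - halos[(cond, +1)]
        fac = 1.0 + sign * beta / 2.0
        for (i, j) in pix:
            if j - i < mu[cond].shape[1] and i < mu[cond].shape[0]:
                mu[cond][i, j - i] *= fac
    return PerturbedField(mu, truth, categories)


def synthetic_bias(n_bins: int, rng, sd: float = 0.15) -> np.ndarray:
    """Multiplicative per-bin bias factors (lognormal, mean-1 normalized)."""
    b = np.clip(rng.lognormal(0.0, sd, size=n_bins), 0.4, 2.5)
    return b / b.mean()


def synthetic_size_factors(max_dist: int, rng) -> np.ndarray:
    """Per-replicate distance-dependent depth factor: a global depth times a
    mild exponential tilt across distance (depth differences affect distance
    scales nonuniformly in real libraries)."""
    depth = rng.uniform(0.7, 1.4)
    tilt = rng.uniform(-0.2, 0.2)
    d = np.arange(max_dist + 1, dtype=float)
    return depth * np.exp(tilt * (d / max_dist - 0.5))


def bias_and_sample(mu: dict, design: StudyDesign, bias: dict,
                    size_factors: dict, dispersion, rngs: dict) -> dict:
    """Draw raw NB counts per pseudoreplicate from the biased mean fields.

    ``dispersion`` is a callable of distance (or a vector over distances);
    ``rngs`` maps replicate -> independent Generator so adding a replicate
    never changes existing draws.
    """
    counts = {}
    for r in design.replicates:
        c = design.condition_of[r]
        field_c = mu[c]
        n_bins, width = field_c.shape
        d = np.arange(width)
        alpha = dispersion(d) if callable(dispersion) else np.asarray(dispersion)
        if not np.all(np.isfinite(alpha)):
            raise ValueError("dispersion undefined at a needed distance")
        b = bias[r]
        shifted = np.full((n_bins, width), np.nan)
        for dd in range(width):
            shifted[: n_bins - dd, dd] = b[dd:]
        mu_biased = field_c * b[:, None] * shifted * size_factors[r][None, :]
        counts[r] = nb_rvs(mu_biased, alpha[None, :], rngs[r])
    return counts


@dataclass
class SimulatedDataset:
    counts: dict
    truth: np.ndarray
    loops: LoopList
    baseline: SyntheticBaseline
    categories: dict
    design: StudyDesign
    bias: dict = field(default_factory=dict)
    size_factors: dict = field(default_factory=dict)


def simulate_dataset(beta: float, p_diff: float, seed: int,
                     n_bins: int = 2000, n_loops: int = 200,
                     min_dist: int = 4, max_dist: int = 500,
                     gamma: float = 1.0, enrichment: float = 4.0,
                     mean_at_max: float = 8.0, n_replicates: int = 2,
                     bin_size: int = 10_000, dispersion=None,
                     with_bias: bool = True) -> SimulatedDataset:
    """End-to-end two-condition simulation with known truth labels.

    One master seed fans out to independent substreams for the baseline, the
    loop category labels, the bias/size-factor structure, and each
    pseudoreplicate's count draws.
    """
    if dispersion is None:
        dispersion = default_dispersion
    ss = np.random.SeedSequence(seed)
    s_base, s_labels, s_struct, s_draws = ss.spawn(4)
    baseline = make_synthetic_baseline(
        n_bins=n_bins, n_loops=n_loops, gamma=gamma, enrichment=enrichment,
        mean_at_max=mean_at_max, min_dist=min_dist, max_dist=max_dist,
        bin_size=bin_size, seed=s_base)
    field_ = label_and_perturb(baseline, beta, p_diff,
                               np.random.default_rng(s_labels))
    reps = {f"{c}{i + 1}": c for c in ("A", "B") for i in range(n_replicates)}
    design = StudyDesign(reps, bin_size=bin_size, min_dist_bins=min_dist,
                         max_dist_bins=max_dist)
    # substreams keyed by (condition index, replicate index) so that adding
    # a replicate leaves every existing replicate's structure and draws
    # unchanged
    max_reps = 64
    struct_children = s_struct.spawn(2 * max_reps)
    draw_children = s_draws.spawn(2 * max_reps)
    bias, size_factors, child_rngs = {}, {}, {}
    for r in design.replicates:
        ci = ("A", "B").index(design.condition_of[r])
        ri = int(r[1:]) - 1
        idx = ci * max_reps + ri
        rng_struct = np.random.default_rng(struct_children[idx])
        if with_bias:
            bias[r] = synthetic_bias(n_bins, rng_struct)
            size_factors[r] = synthetic_size_factors(max_dist, rng_struct)
        else:
            bias[r] = np.ones(n_bins)
            size_factors[r] = np.ones(max_dist + 1)
        child_rngs[r] = np.random.default_rng(draw_children[idx])
    counts = bias_and_sample(field_.mu, design, bias, size_factors,
                             dispersion, child_rngs)
    return SimulatedDataset(counts, field_.truth, baseline.loops, baseline,
                            field_.categories, design, bias, size_factors)


def estimate_truth_prevalence(truth: np.ndarray, loops: LoopList) -> float:
    """Exact fraction of loop-footprint pixels carrying a positive truth label."""
    pix = sorted(loops.union_pixels())
    if not pix:
        return 0.0
    vals = [truth[i, j - i] for (i, j) in pix]
    return float(np.mean(vals))
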