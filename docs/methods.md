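# Methods

## Hi-C branch

### Count model

Binned intrachromosomal counts are modeled as negative binomial:
`X[r,i,j] ~ NB(mu[c(r),i,j] * b[r,i] * b[r,j] * s[r,d], alpha[c(r),d])` with
`d = j - i` the interaction distance in bins.  The NB is parameterized by
mean and dispersion (`Var = mu + alpha mu^2`); `alpha -> 0` is the Poisson
limit, dispatched explicitly below `alpha = 1e-8`.  Chromosomes are
processed independently except dispersion estimation, which pools all
chromosomes.

### Normalization

*Sparse-row filter.* A bin is excluded when it has fewer than 25 nonzero
entries at offsets 1..300 from the diagonal (both directions combined).  The
filter is one-shot, as in standard balancing practice; re-application
removes nothing further on reasonable data.

*Bias vectors.* Per replicate, the filtered symmetric matrix is balanced so
that scaled row sums are equal (tolerance 1e-6 on the relative row-sum
spread, at most 3000 iterations).  The solver is a damped multiplicative
fixed-point iteration — the geometric mean of the current scaling and the
Sinkhorn update `x <- 1/(Ax)` — which converges to the same fixed point as
Newton-type balancing schemes and is robust on the banded, strictly positive
matrices this package produces; the equal-row-sum contract is what tests
pin, not the solver trajectory.  The bias vector is rescaled to mean 1 over
retained bins; bins with bias above 10 or below 0.1 are excluded.  Because a
single extreme bin can skew a mean-based cutoff badly at small matrix sizes,
the cutoff is applied first on the median-normalized vector and then, as
stated, on the mean-1 scale of the remaining bins.

*Size factors.* Pixels with a nonzero count in every replicate and distance
within the tested range are ranked by distance and split into 100
equal-count groups.  Per group and replicate, the factor is the median of
balanced counts divided by their across-replicate geometric mean; per-
distance factors are linear interpolations of the (group mean distance,
factor) anchors, held constant beyond the outermost anchors.  Pixels with a
zero in any replicate are excluded from all further analysis; requiring
all-nonzero pixels keeps the geometric-mean denominator well defined and is
negligible at the sequencing depths the simulator emulates (zero
probability < 2% at the maximum distance).

*Tested pixels.* Normalized counts are `z = x / (b_i b_j s_d)`; a pixel is
tested when its normalized condition mean is at least 1 in **every**
condition, its distance lies in [`min_dist_bins`, `max_dist_bins`] (defaults
4 and 500 bins, i.e. 40 kb – 5 Mb at 10 kb bins), and no touched bin is
excluded.

### Dispersion (distance–dispersion relationship, DDR)

For each condition and distance, counts of all tested pixels at that
distance are pooled and a single dispersion is estimated by qCML:

1. fit each pixel's mean by ML under the current dispersion with the
   combined scaling factors held fixed (vectorized bisection on log mu over
   [1e-9, 1e12]; the score is monotone, so bisection is exact);
2. quantile-map each count from NB(mu k_r, alpha) to NB(mu k_bar, alpha)
   where k_bar is the per-pixel geometric mean of the combined scaling
   factors across the condition's replicates.  The map matches mid-p CDFs
   (`[F(x-1)+F(x)]/2`) and inverts the target mid-CDF by linear
   interpolation between consecutive integers, so pseudocounts are
   continuous and the map is exactly the identity when all scaling factors
   agree;
3. update the dispersion by maximizing the conditional likelihood of the
   pseudocounts given their per-pixel sums, over alpha in [1e-7, 10]
   (bounded scalar search on log alpha, bracket expanded from the previous
   value when the optimum presses an endpoint).

Iteration stops when the dispersion changes by less than 1e-4.  The first
distance starts from 0.01; subsequent distances warm-start from their
neighbour (a pure speed device — the fixed point is unchanged).

Raw per-distance estimates are smoothed by a weighted LOWESS: a centred
rolling sample variance of window 20 gauges each estimate's precision (left
edge filled with the value at `min_dist + 10`, right edge with the interior
maximum — 14 and 491 for the default range); weights are inverse variance to
the 1/4 power, rescaled so the minimum is 1, floored to integers (capped at
1000) and used as duplication counts for a single-pass tricube LOWESS with
fraction `15 / (max(dup) * mean(w))`, clipped so each local window spans
more than one distinct distance (and user-overridable via `--lowess-frac`).
Distances with no tested pixels are linearly interpolated before smoothing
and carry zero duplication weight.  The final curve uses the raw estimates
below the first distance at which they increase, and the LOWESS fit beyond
(floored at 1e-7); if the raw curve never increases the smooth fit is used
everywhere.

### Test, FDR, clustering, classification

Null fit: one shared mean across all replicates (each condition keeping its
own dispersion); alternative: one mean per condition.  `-2 log lambda` is
clipped at zero and referred to chi-square with `|C| - 1` df; all-zero
pixels get p = 1.  Only pixels under the union of the input loop calls are
tested and BH-corrected (pooled across chromosomes).  Significant pixels at
the chosen FDR (default 1%) are clustered by 4-connectivity (edges only —
the strictest reading of direct adjacency); clusters below the minimum size
(default 3) are reported as `unclassified`.  The same clustering is applied
to the insignificant loop pixels, whose retained clusters are labeled
`constitutive`.  Each retained significant pixel takes the condition of its
largest normalized mean; exact ties break toward design order and are
flagged.  With more than two conditions the argmax rule is kept verbatim;
richer labeling is out of scope.

Alternative dispersion providers, used for benchmarking: `poisson`
(dispersion fixed at zero), `global` (one qCML dispersion per condition over
all loop pixels regardless of distance), and `sample-variance` (per-pixel
`alpha = max(1e-7, (s^2 - m)/m^2)` from the normalized within-condition
moments).

### Simulator

`make_synthetic_baseline` builds a normalized mean field
`scale * d^-gamma` (gamma = 1) with `scale` set so the mean at the maximum
tested distance is 8 — a deep-coverage regime in which the all-nonzero
filter is essentially inert — and plants non-overlapping 2x2-pixel loops
(default 200 at 2000 bins; enrichment 4) whose centre distances are uniform
over the tested range so every distance stratum is populated.  Loops are
labeled constitutive with probability `1 - p_diff`, otherwise uniformly one
of up-in-A / down-in-A / up-in-B / down-in-B; member pixels are scaled by
`1 ± beta` in the matching condition and non-loop 4-neighbours by
`1 ± beta/2` (an up-halo wins over a down-halo on the rare overlap).  Truth
is 1 exactly on differential-loop member pixels.  Per-replicate structure
re-imposes lognormal bin biases (sd 0.15, clipped to [0.4, 2.5]) and a
depth factor in [0.7, 1.4] with a mild exponential distance tilt (±0.2),
mimicking the nonuniform way depth differences hit distance scales.  Counts
are NB draws with a distance-dependent dispersion, by default
`0.03 + 0.10 exp(-d/3) + 0.0003 d`: a sharp decrease over the first ~10
bins followed by a slow rise, the shape seen in deep Hi-C data, with
magnitudes giving realistic replicate scatter.  One master seed fans out
into substreams keyed by (condition, replicate index), so adding a
replicate changes nothing else.

The simulator does **not** model TADs/compartments, interchromosomal
contacts, read-level noise, or mappability structure; passing tests
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to those real-data features.

### Evaluation

Scores are `1 - q` against the simulation truth: ROC/AUROC (trapezoid),
observed FDR = FP/(FP+TP) among pixels with `q <= t` (0 when nothing is
called), and power = TPR per threshold.  Distance strata are
[0, 400 kb), [400, 800 kb), [800 kb, inf) on anchor distance (left-closed);
BH is re-run within each stratum before stratified curves so short-range
power cannot inflate long-range FDR.  The low-p diagnostic computes, on a
null simulation, the fraction of each stratum's pixels below the global 5th
percentile of p-values; an unbiased model gives ~5% everywhere.  A single
global dispersion is anti-conservative wherever the true dispersion exceeds
it and conservative elsewhere, so with a dispersion that rises with
distance the low p-values concentrate in the long stratum — the signature
the global-NB comparison reproduces.

## 5C branch

### Mean-variance model and null replicate sets

Inputs are quantile-normalized fragment-level count matrices (normalization
itself is upstream and out of scope).  Per condition, per-interaction sample
means and unbiased variances are pooled across regions into overlapping
distance windows — 12 kb windows / 4 kb step below 150 kb, 24 kb / 8 kb to
600 kb, 60 kb / 24 kb to 1 Mb (windows straddling a regime boundary belong
to their start's regime; interactions beyond 1 Mb reuse the last window).
Within a window, interactions with mean <= 1 or mean more than 2.5 SD above
the window's mean of means are dropped, and the dispersion `A` of
`sigma^2 = A mu^2 + mu` is fit by non-negative least squares through the
origin.  `A` versus window median distance is LOWESS-smoothed (fraction
0.5); underdetermined windows are filled by the smooth.  The simulation
variance blends prediction and observation (`0.5/0.5` by default — enough
smoothing to stabilize two-replicate variances while keeping simulated
pairwise correlations on par with real replicates) and is clamped to at
least the mean so that NB(mean, variance) is parameterizable
(`size = mu^2/(var - mu)`; the clamp collapses to Poisson).  Null replicate
sets are 6 simulated replicates of one condition — by default the condition
with the highest mean fitted dispersion, the conservative choice — assigned
the experimental condition labels.

### Interaction scores

Fragment matrices (real and simulated alike) are balanced with the same
equal-row-sum solver, binned on a 4 kb grid with 16 kb smoothing windows
(arithmetic mean of balanced counts over member fragment pairs), and
corrected by the maximum of a donut and a lower-left local expected
(inner radius p = 2, outer w = 6, same-row/column bands excluded, validity
requiring at least half the footprint; each estimate rescales the regional
per-distance decay curve by the footprint's observed/expected ratio).
Bin pairs within 20 kb are masked before modeling and never reappear.
Observed/expected ratios are fit per region by a two-parameter log-logistic
via maximum likelihood (`scipy.stats.fisk` with location fixed at 0;
at least 50 usable ratios required), giving right-tail p-values,
`IS = -10 log2(p)` and z-scores `Phi^-1(1-p)`.

### Classification with empirical FDR

Background pixels have all-replicate maximum IS below `b = -10 log2(0.8)`;
candidates need every replicate of at least one condition above
`g = -10 log2(0.165)` (strict).  With `Delta[t,u] = min_s IS_t - max_s IS_u`
(the worst-case across-replicate difference), a candidate is class `{t}`
when `Delta[t,u] >= d` against both outside conditions and `t` passes `g`;
class `{t,t'}` when both members beat the remaining condition by `d`, both
pass `g`, and neither beats the other by `d` (the "similar pair" predicate
is isolated in one function); constitutive when all conditions pass `g` and
no ordered difference reaches `d`; remaining candidates are `other`.  The
classes are mutually exclusive by construction.  For each class, `d` sweeps
a grid (default 0.5 to 40 by 0.5) and the empirical FDR is the mean number
of same-class calls on the null replicate sets divided by the calls on the
experimental set (defined 0 when the experimental set has no calls — no
discoveries, no false discoveries); the selected `d` has eFDR closest to
the target while strictly below it, ties toward the smaller `d`.  Final
per-class calls are clustered per region by 4-connectivity with the same
minimum-size rule.

### Benchmarks

One-way fixed-effects ANOVA (classical, not Welch) with BH, with explicit
conventions for degenerate pixels (zero within-group variance with signal
gives p = 0, all-identical gives p = 1, both flagged) to keep NaNs out of
the BH step.  The normal-model LRT treats z-scores as unit-variance normals
with one shift per condition (alternative) or one shared shift (null); the
statistic is computed by direct density evaluation and equals
`sum_c n_c (zbar_c - zbar)^2`, which the tests use as an independent
closed-form oracle; df = `|C| - 1`.  Significant three-condition pixels are
ranked `mu_A' > mu_B' > mu_C'` and labeled `{A'}` when the top gap exceeds
the bottom gap, `{A',B'}` otherwise (equal gaps read as single-condition
and flagged).

## Problem sizes and limitations

The full-scale acceptance checks use the study conditions: 2000-bin
matrices, 500 planted loops, distances 4–500 bins, two pseudoreplicates per
condition; the observed-FDR headline averages three simulations because a
single label draw's differential fraction has binomial SD ~2.2 percentage
points at 500 loops.  Replicated checks (null specificity across 20 seeds,
effect-size monotonicity, model-signature comparisons) use 600–1200 bins
with maximum distance 150 bins; the DDR edge-fill offsets scale with the
stated `min_dist + 10` / `max_dist - 9` rule.  Known limitations: the
asymptotic chi-square reference is approximate at very low means (mitigated
by the mean >= 1 filter); the LOWESS fraction heuristic is exactly that (a
keyword overrides it); dual-class 5C predicates encode one reading of the
"similar pair" notion and are switchable; 2-condition 5C designs drop the
dual classes; the dispersion of real data at unobserved distances is
extrapolated by clamping.
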