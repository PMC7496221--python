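"""Synthetic Hi-C baseline, perturbation labeling and NB count sampling."""

import numpy as np
import pytest

from loopdiff.nb import nb_rvs
from loopdiff.simulate import (estimate_truth_prevalence, label_and_perturb,
                               make_synthetic_baseline, simulate_dataset)


class TestBaseline:
    def test_no_loops_gives_pure_power_law(self):
        b = make_synthetic_baseline(n_bins=100, n_loops=0, max_dist=50, seed=0)
        assert len(b.loops) == 0
        d = np.arange(1, 51)
        expect = 8.0 * 50.0 * d.astype(float) ** -1.0
        assert np.allclose(b.zbar[0, 1:], expect)

    def test_unit_enrichment_leaves_field_unchanged(self):
        plain = make_synthetic_baseline(n_bins=100, n_loops=0, max_dist=50,
                                        seed=1)
        with_loops = make_synthetic_baseline(n_bins=100, n_loops=5,
                                             enrichment=1.0, max_dist=50,
                                             seed=1)
        assert np.allclose(np.nan_to_num(plain.zbar),
                           np.nan_to_num(with_loops.zbar))

    def test_deterministic_given_seed(self):
        b1 = make_synthetic_baseline(n_bins=150, n_loops=10, max_dist=60,
                                     seed=7)
        b2 = make_synthetic_baseline(n_bins=150, n_loops=10, max_dist=60,
                                     seed=7)
        assert np.array_equal(np.nan_to_num(b1.zbar), np.nan_to_num(b2.zbar))
        assert [l.pixels for l in b1.loops] == [l.pixels for l in b2.loops]

    def test_loops_do_not_overlap(self):
        b = make_synthetic_baseline(n_bins=300, n_loops=30, max_dist=100,
                                    seed=3)
        all_pix = [p for lp in b.loops for p in lp.pixels]
        assert len(all_pix) == len(set(all_pix)) == 30 * 4


class TestLabelAndPerturb:
    def _baseline(self, seed=0):
        return make_synthetic_baseline(n_bins=200, n_loops=20, max_dist=80,
                                       seed=seed)

    def test_effect_applied_per_category_with_half_effect_halo(self):
        b = self._baseline()
        field = label_and_perturb(b, beta=0.3, p_diff=1.0,
                                  rng=np.random.default_rng(0))
        loop_union = b.loops.union_pixels()
        for lp in b.loops:
            cat = field.categories[lp.loop_id]
            cond = "A" if cat.endswith("_A") else "B"
            other = "B" if cond == "A" else "A"
            sign = +1 if cat.startswith("up") else -1
            for (i, j) in lp.pixels:
                assert field.mu[cond][i, j - i] == pytest.approx(
                    (1 + sign * 0.3) * b.zbar[i, j - i])
                assert field.mu[other][i, j - i] == pytest.approx(
                    b.zbar[i, j - i])
                assert field.truth[i, j - i] == 1
                # non-loop 4-neighbours carry half the effect, truth 0
                for (ni, nj) in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                    if (ni, nj) in loop_union or nj - ni > 80 or ni < 0:
                        continue
                    assert field.truth[ni, nj - ni] == 0
                    assert field.mu[cond][ni, nj - ni] == pytest.approx(
                        (1 + sign * 0.15) * b.zbar[ni, nj - ni])

    def test_zero_effect_leaves_means_identical(self):
        b = self._baseline(1)
        field = label_and_perturb(b, beta=0.0, p_diff=0.5,
                                  rng=np.random.default_rng(1))
        assert np.array_equal(np.nan_to_num(field.mu["A"]),
                              np.nan_to_num(b.zbar))
        assert np.array_equal(np.nan_to_num(field.mu["B"]),
                              np.nan_to_num(b.zbar))

    def test_constitutive_loops_unchanged_and_unlabeled(self):
        b = self._baseline(2)
        field = label_and_perturb(b, beta=0.5, p_diff=0.0,
                                  rng=np.random.default_rng(2))
        assert field.truth.sum() == 0
        assert all(c == "constitutive" for c in field.categories.values())

    def test_excessive_effect_size_rejected(self):
        with pytest.raises(ValueError):
            label_and_perturb(self._baseline(), beta=1.2, p_diff=0.5,
                              rng=np.random.default_rng(0))


class TestSampling:
    def test_poisson_limit_mean_recovery(self):
        rng = np.random.default_rng(0)
        draws = nb_rvs(np.full(10_000, 100.0), 1e-12, rng)
        assert 97 <= draws.mean() <= 103

    def test_nb_variance_identity(self):
        rng = np.random.default_rng(1)
        draws = nb_rvs(np.full(50_000, 100.0), 0.1, rng)
        expect = 100 + 0.1 * 100 ** 2
        assert abs(draws.var() - expect) / expect < 0.1

    def test_bias_doubles_expected_counts(self):
        sim1 = simulate_dataset(beta=0.0, p_diff=0.0, seed=5, n_bins=120,
                                n_loops=0, max_dist=40, with_bias=False)
        r = sim1.design.replicates[0]
        # identity bias/size factors: mean counts track the baseline field
        valid = np.isfinite(sim1.counts[r])
        ratio = np.nansum(sim1.counts[r][valid]) / np.nansum(
            sim1.baseline.zbar[valid])
        assert ratio == pytest.approx(1.0, rel=0.05)


class TestDataset:
    def test_deterministic_and_stable_under_added_replicate(self):
        a = simulate_dataset(beta=0.3, p_diff=0.4, seed=9, n_bins=150,
                             n_loops=10, max_dist=50)
        b = simulate_dataset(beta=0.3, p_diff=0.4, seed=9, n_bins=150,
                             n_loops=10, max_dist=50)
        for r in a.design.replicates:
            assert np.array_equal(np.nan_to_num(a.counts[r]),
                                  np.nan_to_num(b.counts[r]))
        c = simulate_dataset(beta=0.3, p_diff=0.4, seed=9, n_bins=150,
                             n_loops=10, max_dist=50, n_replicates=3)
        for r in a.design.replicates:
            assert np.array_equal(np.nan_to_num(a.counts[r]),
                                  np.nan_to_num(c.counts[r]))

    @pytest.mark.parametrize("p_diff,expect", [(0.0, 0.0), (1.0, 1.0)])
    def test_truth_prevalence_extremes(self, p_diff, expect):
        sim = simulate_dataset(beta=0.3, p_diff=p_diff, seed=3, n_bins=200,
                               n_loops=20, max_dist=80)
        assert estimate_truth_prevalence(sim.truth, sim.loops) == expect

    def test_truth_prevalence_matches_label_probability(self):
        sim = simulate_dataset(beta=0.3, p_diff=0.4, seed=4, n_bins=500,
                               n_loops=120, max_dist=150)
        prev = estimate_truth_prevalence(sim.truth, sim.loops)
        assert abs(prev - 0.4) < 3 * np.sqrt(0.4 * 0.6 / 120)
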