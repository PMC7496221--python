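"""NB pmf, mean fitting, the likelihood-ratio test, BH, clustering, classes."""

import numpy as np
import pytest
from scipy.stats import chi2, poisson

from loopdiff.nb import fit_mu, nb_logpmf
from loopdiff.nbtest import (bh_fdr, classify_pixels, cluster_pixels,
                             lrt_pixels, sample_variance_alpha)


class TestNbLogpmf:
    def test_unit_mean_unit_dispersion_values(self):
        assert np.exp(nb_logpmf(0, 1, 1))[0] == pytest.approx(0.5, abs=1e-12)
        assert np.exp(nb_logpmf(1, 1, 1))[0] == pytest.approx(0.25, abs=1e-12)

    def test_vanishing_dispersion_matches_poisson(self):
        got = np.exp(nb_logpmf(3, 2, 1e-10))[0]
        assert got == pytest.approx(poisson.pmf(3, 2), abs=1e-8)
        # at alpha = 1e-7 the NB pmf genuinely deviates from Poisson by O(alpha)
        got = np.exp(nb_logpmf(3, 2, 1e-7))[0]
        assert got == pytest.approx(poisson.pmf(3, 2), abs=1e-6)

    def test_zero_mean_point_mass(self):
        assert nb_logpmf(0, 0, 0.5)[0] == 0.0
        with pytest.raises(ValueError):
            nb_logpmf(2, 0, 0.5)

    def test_real_pseudocounts_admitted(self):
        vals = nb_logpmf(np.array([2.0, 2.5, 3.0]), 2.5, 0.3)
        assert np.isfinite(vals).all()
        assert vals[1] > vals[0] or vals[1] > vals[2]  # mode near the mean


class TestFitMu:
    def test_single_observation_scales_count(self):
        for a in (0.0, 0.3, 2.0):
            mu = fit_mu(np.array([[8.0]]), np.array([[2.0]]), a)
            assert mu[0] == pytest.approx(4.0, rel=1e-6)

    def test_poisson_limit_equals_scaled_mean(self):
        x = np.array([[3.0, 5.0, 10.0]])
        k = np.full_like(x, 2.0)
        mu = fit_mu(x, k, 0.0)
        assert mu[0] == pytest.approx(6.0 / 2.0, rel=1e-8)

    def test_all_zero_counts_give_zero(self):
        assert fit_mu(np.zeros((1, 3)), np.ones((1, 3)), 0.1)[0] == 0.0


class TestLRT:
    def test_identical_conditions_give_null_result(self):
        x = np.tile([4.0, 7.0, 4.0, 7.0], (3, 1))  # both conditions see (4, 7)
        k = np.ones_like(x)
        a = np.full_like(x, 0.2)
        stat, p, mu0, mu_alt = lrt_pixels(x, k, a, np.array([0, 0, 1, 1]), 2)
        assert np.allclose(stat, 0.0, atol=1e-8)
        assert np.allclose(p, 1.0, atol=1e-6)
        assert np.allclose(mu_alt[:, 0], mu_alt[:, 1])
        assert np.allclose(mu_alt[:, 0], mu0)

    def test_poisson_limit_matches_closed_form_oracle(self):
        rng = np.random.default_rng(0)
        n = 50
        x = rng.poisson(20, size=(n, 4)).astype(float)
        k = np.ones_like(x)
        cond = np.array([0, 0, 1, 1])
        stat, p, _, _ = lrt_pixels(x, k, np.zeros_like(x), cond, 2)

        def pois_ll(xx, mu):
            mu = max(mu, 1e-300)
            return (xx * np.log(mu) - mu).sum()

        for row in range(n):
            m0 = x[row].mean()
            mA, mB = x[row, :2].mean(), x[row, 2:].mean()
            oracle = 2 * (pois_ll(x[row, :2], mA) + pois_ll(x[row, 2:], mB)
                          - pois_ll(x[row], m0))
            assert stat[row] == pytest.approx(oracle, abs=1e-6)

    def test_three_conditions_use_two_degrees_of_freedom(self):
        x = np.array([[1.0, 2, 30, 31, 60, 62]])
        k = np.ones_like(x)
        a = np.full_like(x, 0.05)
        cond = np.array([0, 0, 1, 1, 2, 2])
        stat, p, _, _ = lrt_pixels(x, k, a, cond, 3)
        assert p[0] == pytest.approx(chi2.sf(stat[0], 2))

    def test_all_zero_pixel_forced_to_p_one(self):
        x = np.zeros((1, 4))
        stat, p, mu0, _ = lrt_pixels(x, np.ones_like(x), np.full_like(x, 0.1),
                                     np.array([0, 0, 1, 1]), 2)
        assert stat[0] == 0.0 and p[0] == 1.0 and mu0[0] == 0.0

    def test_invariant_to_replicate_relabeling(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(30, size=(20, 4)).astype(float)
        k = rng.uniform(0.8, 1.2, size=x.shape)
        a = np.full_like(x, 0.1)
        cond = np.array([0, 0, 1, 1])
        stat1, _, _, _ = lrt_pixels(x, k, a, cond, 2)
        perm = [1, 0, 3, 2]  # swap replicates within each condition
        stat2, _, _, _ = lrt_pixels(x[:, perm], k[:, perm], a, cond, 2)
        assert np.allclose(stat1, stat2, atol=1e-8)

    def test_null_p_values_are_uniform(self):
        """Well-specified NB null: the empirical CDF of p hugs the diagonal."""
        rng = np.random.default_rng(2)
        n = 20000
        a = 0.1
        x = rng.negative_binomial(1 / a, 1 / (1 + a * 20),
                                  size=(n, 4)).astype(float)
        _, p, _, _ = lrt_pixels(x, np.ones_like(x), np.full_like(x, a),
                                np.array([0, 0, 1, 1]), 2)
        grid = np.linspace(0.05, 0.95, 19)
        ecdf = np.array([(p <= g).mean() for g in grid])
        assert np.abs(ecdf - grid).max() < 0.02


class TestBH:
    def test_step_up_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_and_degenerate_inputs(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([]).size == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        q = bh_fdr(rng.uniform(size=100))
        called_strict = set(np.flatnonzero(q <= 0.01))
        called_loose = set(np.flatnonzero(q <= 0.05))
        assert called_strict <= called_loose


class TestClustering:
    def test_edge_adjacent_triplet_retained(self):
        clusters, discarded = cluster_pixels([(1, 5), (1, 6), (2, 5)], 3)
        assert clusters == [frozenset({(1, 5), (1, 6), (2, 5)})]
        assert discarded == set()

    def test_isolated_pixel_discarded(self):
        clusters, discarded = cluster_pixels([(1, 5), (4, 9), (4, 10), (5, 9)], 3)
        assert len(clusters) == 1
        assert discarded == {(1, 5)}

    def test_diagonal_neighbors_not_connected(self):
        clusters, discarded = cluster_pixels([(1, 5), (2, 6)], 1)
        assert len(clusters) == 2


class TestClassify:
    def test_argmax_and_tie_flag(self):
        labels, ties = classify_pixels(
            {(0, 5): [5.0, 2.0], (1, 6): [3.0, 3.0]}, ["A", "B"])
        assert labels[(0, 5)] == "A"
        assert labels[(1, 6)] == "A" and (1, 6) in ties


class TestSampleVarianceDispersion:
    def test_moment_matching_formula(self):
        assert sample_variance_alpha(2.0, 6.0)[()] == pytest.approx(1.0)

    def test_underdispersed_floored(self):
        assert sample_variance_alpha(2.0, 1.5)[()] == pytest.approx(1e-7)
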