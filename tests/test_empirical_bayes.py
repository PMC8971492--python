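"""Per-cluster empirical Bayes adjustment: standardization, hyperpriors,
shrinkage and the assembled cluster correction."""

import numpy as np
import pytest

from cytobatch.empirical_bayes import (
    ConfoundedDesignError,
    Hyperpriors,
    SmallBatchError,
    adjust_cluster,
    batch_moments,
    combat_cluster,
    estimate_hyperpriors,
    fit_standardization,
    shrink_parametric,
)


def two_batches(n=200, m=6, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    Y = rng.normal(0, 1, (n, m))
    batches = np.repeat(["b1", "b2"], n // 2)
    Y[n // 2 :] += shift
    return Y, batches


class TestStandardization:
    def test_identical_batches_give_standard_scale(self):
        Y, batches = two_batches(n=2000, seed=1)
        fit = fit_standardization(Y, batches)
        np.testing.assert_allclose(fit.Z.mean(axis=0), 0, atol=0.01)
        np.testing.assert_allclose(fit.Z.var(axis=0), 1, atol=0.05)

    def test_constant_marker_flagged_and_zeroed(self):
        Y, batches = two_batches()
        Y[:, 2] = 7.0
        fit = fit_standardization(Y, batches)
        assert fit.constant_mask[2]
        assert np.all(fit.Z[:, 2] == 0)

    def test_additive_shift_appears_in_gamma(self):
        Y, batches = two_batches(n=4000, shift=0.5, seed=2)
        fit = fit_standardization(Y, batches)
        gamma_hat, _ = batch_moments(fit)
        diff = gamma_hat[1] - gamma_hat[0]
        np.testing.assert_allclose(diff * fit.sigma_hat, 0.5, atol=0.05)

    def test_small_batch_rejected(self):
        Y = np.random.default_rng(0).normal(0, 1, (5, 3))
        with pytest.raises(SmallBatchError):
            fit_standardization(Y, ["a", "a", "a", "a", "b"])

    def test_confounded_covariate_rejected(self):
        Y, batches = two_batches()
        with pytest.raises(ConfoundedDesignError):
            fit_standardization(Y, batches, covariates=batches)


class TestHyperpriors:
    def test_gamma_moments_hand_example(self):
        hp = estimate_hyperpriors(
            np.array([[0.1, 0.3]]), np.array([[1.0, 2.0]])
        )
        np.testing.assert_allclose(hp.gamma_bar, [0.2])
        np.testing.assert_allclose(hp.tau2, [0.02])

    def test_inverse_gamma_moment_formulas(self):
        # delta2_hat with mean 1 and variance 1 -> a = 3, b = 2
        d2 = np.array([0.0, 0.775255128608411, 1.0, 1.224744871391589, 2.0])
        d2 += 1 - d2.mean()
        d2 = d2 * (1 / d2.std(ddof=1))
        d2 += 1 - d2.mean()
        hp = estimate_hyperpriors(np.zeros((1, 5)), d2[None, :])
        np.testing.assert_allclose(hp.a_prior, [3.0], atol=1e-10)
        np.testing.assert_allclose(hp.b_prior, [2.0], atol=1e-10)

    def test_zero_spread_flags_degenerate_prior(self):
        hp = estimate_hyperpriors(np.array([[0.1, 0.2]]), np.array([[1.5, 1.5]]))
        assert hp.s2_zero[0]

    def test_single_marker_rejected(self):
        with pytest.raises(ValueError, match="2 markers"):
            estimate_hyperpriors(np.array([[0.1]]), np.array([[1.0]]))


class TestShrinkage:
    def _fit(self):
        Y, batches = two_batches(n=300, shift=0.4, seed=3)
        fit = fit_standardization(Y, batches)
        gamma_hat, delta2_hat = batch_moments(fit)
        return fit, gamma_hat, delta2_hat

    def test_flat_prior_limit_recovers_gamma_hat(self):
        fit, gamma_hat, delta2_hat = self._fit()
        hp = estimate_hyperpriors(gamma_hat, delta2_hat)
        hp_flat = Hyperpriors(
            hp.gamma_bar, np.full_like(hp.tau2, np.inf),
            hp.a_prior, hp.b_prior, hp.s2_zero,
        )
        g_star, _, _, _ = shrink_parametric(
            fit.Z, fit.batch_rows, gamma_hat, delta2_hat, hp_flat
        )
        np.testing.assert_allclose(g_star, gamma_hat, atol=1e-10)

    def test_zero_tau2_collapses_to_gamma_bar(self):
        fit, gamma_hat, delta2_hat = self._fit()
        hp = estimate_hyperpriors(gamma_hat, delta2_hat)
        hp0 = Hyperpriors(
            hp.gamma_bar, np.zeros_like(hp.tau2),
            hp.a_prior, hp.b_prior, hp.s2_zero,
        )
        g_star, _, _, _ = shrink_parametric(
            fit.Z, fit.batch_rows, gamma_hat, delta2_hat, hp0
        )
        for i in range(g_star.shape[0]):
            np.testing.assert_allclose(g_star[i], hp.gamma_bar[i], atol=1e-12)

    def test_shrinkage_is_toward_the_prior_mean(self):
        fit, gamma_hat, delta2_hat = self._fit()
        hp = estimate_hyperpriors(gamma_hat, delta2_hat)
        g_star, _, _, _ = shrink_parametric(
            fit.Z, fit.batch_rows, gamma_hat, delta2_hat, hp
        )
        assert np.all(
            np.abs(g_star - hp.gamma_bar[:, None])
            <= np.abs(gamma_hat - hp.gamma_bar[:, None]) + 1e-12
        )

    def test_degenerate_scale_prior_keeps_delta_hat(self):
        fit, gamma_hat, delta2_hat = self._fit()
        d2 = np.full_like(delta2_hat, 1.3)
        hp = estimate_hyperpriors(gamma_hat, d2)
        _, d_star, _, _ = shrink_parametric(
            fit.Z, fit.batch_rows, gamma_hat, d2, hp
        )
        np.testing.assert_array_equal(d_star, d2)


class TestAdjustment:
    def test_identity_when_no_batch_effect_parameters(self):
        Y, batches = two_batches(seed=4)
        fit = fit_standardization(Y, batches)
        gamma0 = np.zeros((2, Y.shape[1]))
        delta1 = np.ones((2, Y.shape[1]))
        np.testing.assert_allclose(
            adjust_cluster(fit, gamma0, delta1, Y), Y, atol=1e-10
        )

    def test_mean_only_preserves_batch_variances(self):
        Y, batches = two_batches(n=1000, shift=0.8, seed=5)
        y_star, _ = combat_cluster(Y, batches, mean_only=True)
        for rows in (slice(0, 500), slice(500, 1000)):
            np.testing.assert_allclose(
                y_star[rows].var(axis=0), Y[rows].var(axis=0), rtol=1e-6
            )

    def test_additive_shift_removed(self):
        Y, batches = two_batches(n=2000, shift=0.5, seed=6)
        y_star, _ = combat_cluster(Y, batches)
        means = [y_star[:1000].mean(axis=0), y_star[1000:].mean(axis=0)]
        np.testing.assert_allclose(means[0], means[1], atol=1e-3 + 0.05)


class TestClusterContract:
    def test_single_batch_identity_with_warning(self):
        Y = np.random.default_rng(0).normal(0, 1, (50, 4))
        with pytest.warns(UserWarning, match="single batch"):
            y_star, rep = combat_cluster(Y, ["b1"] * 50)
        np.testing.assert_array_equal(y_star, Y)
        assert not rep["corrected"]

    def test_eight_cells_completes_finite(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(0, 1, (8, 10))
        y_star, rep = combat_cluster(Y, ["b1"] * 4 + ["b2"] * 4)
        assert np.all(np.isfinite(y_star))
        assert rep["corrected"]

    def test_undersized_batch_leaves_cluster_uncorrected(self):
        Y = np.random.default_rng(2).normal(0, 1, (10, 4))
        with pytest.warns(UserWarning, match="<2 cells"):
            y_star, rep = combat_cluster(Y, ["b1"] * 9 + ["b2"])
        np.testing.assert_array_equal(y_star, Y)
        assert not rep["corrected"]

    def test_identical_batches_near_identity(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(0, 1, (1000, 8))
        y_star, _ = combat_cluster(Y, ["b1"] * 500 + ["b2"] * 500)
        assert np.abs(y_star - Y).mean() < 0.05

    def test_confounded_covariate_falls_back_without_it(self):
        Y, batches = two_batches(n=400, shift=0.5, seed=7)
        y_star, rep = combat_cluster(Y, batches, covariates=batches)
        assert rep["corrected"]
        assert any("confounded" in w for w in rep["warnings"])
        direct, _ = combat_cluster(Y, batches)
        np.testing.assert_allclose(y_star, direct, atol=1e-12)

    def test_covariate_effect_preserved(self):
        # condition effect orthogonal to batch must survive correction
        rng = np.random.default_rng(8)
        n = 2000
        batches = np.repeat(["b1", "b2"], n // 2)
        cond = np.tile(["HD", "CLL"], n // 2)
        effect = 1.0
        Y = rng.normal(0, 1, (n, 5))
        Y[cond == "CLL"] += effect
        Y[batches == "b2"] += 0.6  # batch effect on top
        y_star, _ = combat_cluster(Y, batches, covariates=cond)
        recovered = (
            y_star[cond == "CLL"].mean(axis=0) - y_star[cond == "HD"].mean(axis=0)
        )
        np.testing.assert_allclose(recovered, effect, rtol=0.10)

    def test_single_marker_non_eb_fallback(self):
        Y, batches = two_batches(n=400, m=1, shift=0.7, seed=9)
        y_star, rep = combat_cluster(Y, batches)
        assert rep["corrected"]
        assert any("one marker" in w for w in rep["warnings"])
        assert abs(y_star[:200].mean() - y_star[200:].mean()) < 0.05
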