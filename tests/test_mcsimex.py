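"""The simulation-extrapolation estimator and its variance machinery."""

import numpy as np
import pytest

from misclasscal import (
    MisclassMatrix,
    ModelSpec,
    SimexConfig,
    attach_survival_outcome,
    estimate_step,
    fit_extrapolant,
    fit_naive,
    mcsimex,
    sample_mixture,
    simulate_noise_step,
    two_class_mixture,
    variance_bootstrap,
    variance_jackknife,
)
from misclasscal.mcsimex_core import extrapolate

SPEC = ModelSpec("logistic", 2)


@pytest.fixture(scope="module")
def noisy_logistic():
    """Labels with known symmetric 20% misclassification, logistic outcome."""
    from misclasscal import noisy_binary_labels

    true, corrupted, y = noisy_binary_labels(2000, 0.2, seed=30)
    pi = MisclassMatrix(np.array([[0.8, 0.2], [0.2, 0.8]]))
    return true, corrupted, y, pi


class TestNoiseStep:
    def test_identity_matrix_keeps_labels(self):
        labels = np.tile([1, 2], 50)
        sets = simulate_noise_step(labels, MisclassMatrix(np.eye(2)), 1.5, B=4, seed=0)
        assert np.array_equal(sets, np.tile(labels, (4, 1)))

    def test_flip_fraction_matches_power(self):
        labels = np.ones(100_000, dtype=int)
        pi = MisclassMatrix(np.array([[0.8, 0.2], [0.2, 0.8]]))
        sets = simulate_noise_step(labels, pi, 1.0, B=1, seed=1)
        frac = np.mean(sets[0] != labels)
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 100_000)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            simulate_noise_step(np.array([1, 2]), MisclassMatrix(np.eye(2)), 1.0, B=0)


class TestEstimateStep:
    def test_identical_sets_equal_single_fit(self, noisy_logistic):
        _, corrupted, y, _ = noisy_logistic
        sets = np.tile(corrupted, (5, 1))
        mean, per_b, _ = estimate_step(y, sets, SPEC)
        single = fit_naive(y, corrupted, SPEC).coefficients
        np.testing.assert_allclose(mean, single, atol=1e-10)
        assert per_b.shape == (5, 2)

    def test_permutation_invariant(self, noisy_logistic):
        _, corrupted, y, pi = noisy_logistic
        sets = simulate_noise_step(corrupted, pi, 1.0, B=6, seed=2)
        a, *_ = estimate_step(y, sets, SPEC)
        b, *_ = estimate_step(y, sets[::-1], SPEC)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_attenuation_grows_with_lambda(self, noisy_logistic):
        """More injected label noise shrinks the class effect toward zero."""
        _, corrupted, y, pi = noisy_logistic
        mags = []
        for lam in (0.5, 1.0, 1.5, 2.0):
            sets = simulate_noise_step(corrupted, pi, lam, B=30, seed=3)
            mean, *_ = estimate_step(y, sets, SPEC)
            mags.append(abs(mean[1]))
        assert np.all(np.diff(mags) < 0)


class TestExtrapolant:
    def test_exact_quadratic_recovery(self):
        lam = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        true_gamma = np.array([[1.0, -0.7, 0.12]])
        est = (true_gamma[0, 0] + true_gamma[0, 1] * lam + true_gamma[0, 2] * lam**2)[:, None]
        gamma = fit_extrapolant(lam, est, "quadratic")
        np.testing.assert_allclose(gamma, true_gamma, atol=1e-8)
        assert extrapolate(gamma, -1.0)[0] == pytest.approx(1.0 + 0.7 + 0.12, abs=1e-8)

    def test_constant_estimates_give_flat_curve(self):
        lam = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        gamma = fit_extrapolant(lam, np.full((5, 1), 3.3), "quadratic")
        np.testing.assert_allclose(gamma[0], [3.3, 0.0, 0.0], atol=1e-10)

    def test_three_points_interpolated_exactly(self):
        lam = np.array([0.0, 1.0, 2.0])
        est = np.array([[2.0], [1.1], [0.9]])
        gamma = fit_extrapolant(lam, est, "quadratic")
        D = np.column_stack([np.ones(3), lam, lam**2])
        np.testing.assert_allclose(D @ gamma[0], est[:, 0], atol=1e-10)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="singular|degenerate"):
            fit_extrapolant([1.0, 1.0, 1.0], np.ones((3, 1)), "quadratic")

    def test_loglinear_requires_constant_sign(self):
        with pytest.raises(ValueError, match="sign"):
            fit_extrapolant([0.0, 1.0, 2.0], np.array([[1.0], [-1.0], [0.5]]), "loglinear")


class TestMcsimex:
    def test_identity_pi_is_fixed_point(self, noisy_logistic):
        """With no misclassification the corrected estimate IS the naive one."""
        _, corrupted, y, _ = noisy_logistic
        res = mcsimex(y, corrupted, MisclassMatrix(np.eye(2)), SPEC,
                      SimexConfig(B=10, seed=4), variance="jackknife")
        np.testing.assert_allclose(res.corrected, res.naive_fit.coefficients, atol=1e-10)
        np.testing.assert_allclose(res.standard_errors, res.naive_fit.standard_errors,
                                   rtol=0.10)

    def test_deterministic_given_seed(self, noisy_logistic):
        _, corrupted, y, pi = noisy_logistic
        a = mcsimex(y, corrupted, pi, SPEC, SimexConfig(B=10, seed=5))
        b = mcsimex(y, corrupted, pi, SPEC, SimexConfig(B=10, seed=5))
        np.testing.assert_array_equal(a.corrected, b.corrected)

    def test_corrected_reduces_known_attenuation(self):
        """With the true noise matrix, the correction beats the naive estimate
        in nearly every run (large-n oracle check on 40 seeds)."""
        from misclasscal import noisy_binary_labels

        pi = MisclassMatrix(np.array([[0.8, 0.2], [0.2, 0.8]]))
        wins = 0
        for seed in range(40):
            _, corrupted, y = noisy_binary_labels(2000, 0.2, seed=seed)
            res = mcsimex(y, corrupted, pi, SPEC, SimexConfig(B=30, seed=seed))
            wins += abs(res.corrected[1] - 2) < abs(res.naive_fit.coefficients[1] - 2)
        assert wins >= 38

    def test_result_invariant_corrected_equals_curve_at_minus_one(self, noisy_logistic):
        _, corrupted, y, pi = noisy_logistic
        res = mcsimex(y, corrupted, pi, SPEC, SimexConfig(B=10, seed=6))
        lams, vals = res.curve(-1.0, 2.0, 7)
        assert lams[0] == -1.0
        np.testing.assert_allclose(vals[0], res.corrected, atol=1e-10)


class TestVariance:
    def test_jackknife_needs_two_refits(self, noisy_logistic):
        _, corrupted, y, pi = noisy_logistic
        res = mcsimex(y, corrupted, pi, SPEC, SimexConfig(B=1, seed=7))
        with pytest.raises(ValueError, match="two refits"):
            variance_jackknife(res)

    def test_jackknife_ses_positive(self, noisy_logistic):
        _, corrupted, y, pi = noisy_logistic
        res = mcsimex(y, corrupted, pi, SPEC, SimexConfig(B=20, seed=8),
                      variance="jackknife")
        assert np.all(res.standard_errors > 0)
        assert res.variance_method == "jackknife"

    def test_bootstrap_ci_wider_than_jackknife_on_imbalanced_survival(self):
        """The full bootstrap propagates the uncertainty of the estimated
        noise matrix; the jackknife does not and is anticonservative."""
        mix = two_class_mixture(0.2)
        d = sample_mixture(mix, 400, seed=9)
        d = attach_survival_outcome(d, 0.5, seed=10)
        spec = ModelSpec("cox", 2)
        cfg = SimexConfig(B=20, seed=11)
        boot = variance_bootstrap(d.features, (d.time, d.event), d.true_labels,
                                  spec, cfg, n_boot=20, seed=12)
        from misclasscal import align_labels, estimate_from_fitted_clustering, fit_gmm

        a = align_labels(fit_gmm(d.features, 2, seed=13), d.true_labels)
        pi = estimate_from_fitted_clustering(a, 20_000, seed=14)
        jk = mcsimex((d.time, d.event), a.hard_labels, pi, spec, cfg,
                     variance="jackknife")
        boot_width = boot.ci_95[0, 1] - boot.ci_95[0, 0]
        jk_width = jk.ci_95[0, 1] - jk.ci_95[0, 0]
        assert boot_width > jk_width

    def test_bootstrap_ci_contains_median(self, separable_features):
        feats, labels = separable_features
        rng = np.random.default_rng(15)
        y = (rng.random(labels.size) < np.where(labels == 2, 0.7, 0.3)).astype(int)
        res = variance_bootstrap(feats, y, labels, SPEC, SimexConfig(B=10, seed=16),
                                 n_boot=8, seed=17)
        assert np.all(res.ci_95[:, 0] <= res.point_median)
        assert np.all(res.point_median <= res.ci_95[:, 1])
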