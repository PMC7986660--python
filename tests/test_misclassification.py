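"""Misclassification matrix: powers, existence, estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from misclasscal import (
    MisclassMatrix,
    PowerExistenceError,
    align_labels,
    check_existence,
    estimate_from_fitted_clustering,
    estimate_out_of_bag,
    fit_gmm,
    matrix_power,
    sample_mixture,
    spectral_power,
)


def sym2(diag: float) -> MisclassMatrix:
    return MisclassMatrix(np.array([[diag, 1 - diag], [1 - diag, diag]]))


class TestMatrixPower:
    def test_zeroth_power_is_identity(self):
        np.testing.assert_allclose(matrix_power(sym2(0.8), 0).matrix, np.eye(2))

    def test_first_power_is_input(self):
        pi = sym2(0.8)
        np.testing.assert_allclose(matrix_power(pi, 1).matrix, pi.matrix)

    def test_square_matches_repeated_multiplication(self):
        pi = sym2(0.8)
        # 0.8^2 + 0.2^2 = 0.68 on the diagonal
        np.testing.assert_allclose(
            matrix_power(pi, 2).matrix, pi.matrix @ pi.matrix, atol=1e-10
        )
        assert matrix_power(pi, 2).matrix[0, 0] == pytest.approx(0.68)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        a=st.floats(0.0, 2.0),
        b=st.floats(0.0, 2.0),
        seed=st.integers(0, 10_000),
        m=st.integers(2, 4),
    )
    def test_semigroup_property(self, a, b, seed, m):
        """Pi^(a+b) = Pi^a Pi^b whenever the fractional powers exist (integer
        exponents independently checkable by repeated multiplication).

        Matrices are built from a symmetric strongly diagonally dominant core,
        whose column normalization is similar to a positive-definite symmetric
        matrix and hence has a real positive spectrum."""
        rng = np.random.default_rng(seed)
        S = rng.random((m, m))
        S = (S + S.T) / 2 + 2 * m * np.eye(m)
        pi = MisclassMatrix(S / S.sum(axis=0, keepdims=True))
        lhs = matrix_power(pi, a + b).matrix
        rhs = matrix_power(pi, a).matrix @ matrix_power(pi, b).matrix
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_integer_power_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        M = rng.random((3, 3)) + 3 * np.eye(3)
        pi = MisclassMatrix(M / M.sum(axis=0, keepdims=True))
        brute = np.linalg.multi_dot([pi.matrix] * 3)
        np.testing.assert_allclose(matrix_power(pi, 3).matrix, brute, atol=1e-10)

    def test_negative_eigenvalue_fractional_power_rejected(self):
        with pytest.raises(PowerExistenceError):
            matrix_power(sym2(0.4), 0.5)  # eigenvalues 1 and -0.2

    def test_spectral_reconstruction_invariant(self):
        sp = spectral_power(sym2(0.8), 1.5)
        recon = sp.eigenvectors @ np.diag(sp.eigenvalues**1.5) @ np.linalg.inv(sp.eigenvectors)
        np.testing.assert_allclose(recon, sp.matrix, atol=1e-8)


class TestExistence:
    def test_identity_ok(self):
        assert check_existence(MisclassMatrix(np.eye(2)), 3.0).ok

    def test_low_diagonal_not_ok(self):
        rep = check_existence(sym2(0.4), 2.0)
        assert not rep.ok and not rep.eigenvalues_real_positive

    @pytest.mark.parametrize("diag", [0.55, 0.7, 0.9])
    def test_dominant_diagonal_ok_on_dense_grid(self, diag):
        """2x2 symmetric with diagonal > 0.5 has eigenvalues {1, 2d-1 > 0}
        and stays nonnegative for every lambda >= 0."""
        rep = check_existence(sym2(diag), 4.0, n_grid=401)
        assert rep.ok and rep.min_entry >= -1e-10


class TestValidation:
    def test_non_column_stochastic_rejected(self):
        with pytest.raises(ValueError, match="column"):
            MisclassMatrix(np.array([[0.8, 0.3], [0.1, 0.7]]))

    def test_row_stochastic_roundtrip(self):
        pi = sym2(0.75)
        np.testing.assert_allclose(
            MisclassMatrix.from_row_stochastic(pi.to_row_stochastic()).matrix, pi.matrix
        )

    def test_csv_roundtrip(self, tmp_path):
        pi = sym2(0.8)
        path = tmp_path / "pi.csv"
        pi.to_csv(path)
        np.testing.assert_allclose(MisclassMatrix.from_csv(path).matrix, pi.matrix)


class TestMonteCarloEstimate:
    def test_separable_model_gives_near_identity(self, separable_features):
        feats, labels = separable_features
        a = align_labels(fit_gmm(feats, 2, seed=0), labels)
        pi = estimate_from_fitted_clustering(a, 20_000, seed=1)
        assert pi.matrix[0, 1] < 0.001 and pi.matrix[1, 0] < 0.001

    def test_balanced_scenario_matches_gaussian_overlap(self, balanced_mixture):
        """Diagonal of the estimated matrix approximates 1 - Phi(-1): the
        within-class accuracy of the optimal rule for two unit Gaussians two
        apart."""
        diags = []
        for seed in range(3):
            d = sample_mixture(balanced_mixture, 1000, seed=seed)
            a = align_labels(fit_gmm(d.features, 2, seed=seed), d.true_labels)
            diags.append(np.diag(estimate_from_fitted_clustering(a, 50_000, seed=seed).matrix))
        assert abs(np.mean(diags) - (1 - norm.cdf(-1))) < 0.03

    def test_zero_draws_rejected(self, separable_features):
        feats, labels = separable_features
        a = fit_gmm(feats, 2, seed=2)
        with pytest.raises(ValueError, match="n_mc"):
            estimate_from_fitted_clustering(a, 0)

    def test_monte_carlo_error_shrinks_with_draws(self, balanced_dataset):
        """Quadrupling the draws roughly halves the entry-wise spread."""
        a = align_labels(fit_gmm(balanced_dataset.features, 2, seed=3),
                         balanced_dataset.true_labels)
        small = [estimate_from_fitted_clustering(a, 2000, seed=s).matrix[0, 0]
                 for s in range(12)]
        large = [estimate_from_fitted_clustering(a, 8000, seed=100 + s).matrix[0, 0]
                 for s in range(12)]
        ratio = np.std(small, ddof=1) / np.std(large, ddof=1)
        assert 1.2 < ratio < 3.5

    def test_columns_sum_to_one_exactly(self, balanced_dataset):
        a = align_labels(fit_gmm(balanced_dataset.features, 2, seed=4),
                         balanced_dataset.true_labels)
        pi = estimate_from_fitted_clustering(a, 10_000, seed=5)
        np.testing.assert_allclose(pi.matrix.sum(axis=0), 1.0, atol=1e-12)


class TestOutOfBag:
    def test_separable_data_yields_identity(self, separable_features):
        feats, labels = separable_features
        res = estimate_out_of_bag(feats, labels, n_boot=5, m=2, seed=6)
        for M in res.matrices:
            assert np.diag(M.matrix).min() > 0.99

    def test_single_replicate_deterministic(self, separable_features):
        feats, labels = separable_features
        a = estimate_out_of_bag(feats, labels, n_boot=1, m=2, seed=7)
        b = estimate_out_of_bag(feats, labels, n_boot=1, m=2, seed=7)
        np.testing.assert_array_equal(a.matrices[0].matrix, b.matrices[0].matrix)

    def test_average_is_column_stochastic(self, balanced_dataset):
        res = estimate_out_of_bag(
            balanced_dataset.features[:400], balanced_dataset.true_labels[:400],
            n_boot=6, m=2, seed=8,
        )
        np.testing.assert_allclose(res.average.matrix.sum(axis=0), 1.0, atol=1e-10)
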