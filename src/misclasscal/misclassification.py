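"""The misclassification matrix Pi and its real powers.

Pi is COLUMN-stochastic here: entry (i, j) is P(observed class = i | true
class = j), i.e. each column is the error distribution of one true class.
Beware that the R ``simex`` package stores the transpose (rows condition on
the true class); ``MisclassMatrix.to_row_stochastic`` /
``MisclassMatrix.from_row_stochastic`` convert between the conventions.

Real (non-integer) powers Pi^lambda are computed through the spectral
decomposition Pi = E diag(Lambda) E^-1, so Pi^lambda = E diag(Lambda^lambda)
E^-1. This requires real, strictly positive eigenvalues, and for the power to
remain a misclassification matrix its entries must stay nonnegative;
``check_existence`` reports both conditions.

Two estimators of Pi are provided, both matching the simulation workflow:
a parametric Monte-Carlo estimate from a fitted clustering model, and an
out-of-bag bootstrap estimate against a reference labelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, align_labels, fit_gmm, posterior_from_mixture
from .synthetic_data import MixtureModel

__all__ = [
    "MisclassMatrix",
    "PowerExistenceError",
    "ExistenceReport",
    "SpectralPower",
    "matrix_power",
    "spectral_power",
    "check_existence",
    "estimate_from_fitted_clustering",
    "estimate_out_of_bag",
    "OutOfBagResult",
]

_IMAG_TOL = 1e-10


class PowerExistenceError(ValueError):
    """Pi^lambda is undefined: eigenvalues must be real and strictly positive
    (and entries nonnegative) for the spectral power to be a misclassification
    matrix."""


@dataclass(frozen=True)
class MisclassMatrix:
    """Column-stochastic m x m misclassification matrix."""

    matrix: np.ndarray
    validate: bool = True

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", M)
        if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] < 2:
            raise ValueError("misclassification matrix must be square, m >= 2")
        if self.validate:
            if np.any(M < -1e-12) or np.any(M > 1 + 1e-12):
                raise ValueError("entries must be probabilities in [0, 1]")
            if not np.allclose(M.sum(axis=0), 1.0, atol=1e-8):
                raise ValueError("columns must sum to 1 (column-stochastic)")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    def column(self, true_class: int) -> np.ndarray:
        """Error distribution of 1-based ``true_class``."""
        return self.matrix[:, true_class - 1]

    # -- convention converters -------------------------------------------------
    def to_row_stochastic(self) -> np.ndarray:
        """Transpose into the rows-condition-on-truth convention (R simex)."""
        return self.matrix.T.copy()

    @classmethod
    def from_row_stochastic(cls, matrix: np.ndarray) -> "MisclassMatrix":
        return cls(np.asarray(matrix, dtype=float).T)

    # -- IO --------------------------------------------------------------------
    def to_csv(self, path) -> None:
        labels = [str(h) for h in range(1, self.m + 1)]
        pd.DataFrame(self.matrix, index=labels, columns=labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "MisclassMatrix":
        return cls(pd.read_csv(path, index_col=0).to_numpy(dtype=float))


def _spectral(pi: MisclassMatrix):
    vals, vecs = np.linalg.eig(pi.matrix)
    if np.any(np.abs(vals.imag) > _IMAG_TOL):
        raise PowerExistenceError(
            "complex eigenvalues: the spectral power of this matrix is undefined"
        )
    return vals.real, vecs.real


@dataclass(frozen=True)
class SpectralPower:
    """Pi^lambda together with the decomposition that produced it."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    lam: float
    matrix: np.ndarray

    def __post_init__(self) -> None:
        recon = self.eigenvectors @ np.diag(self.eigenvalues**self.lam) @ np.linalg.inv(
            self.eigenvectors
        )
        if not np.allclose(recon, self.matrix, atol=1e-8):
            raise ValueError("spectral reconstruction does not match the matrix")


def spectral_power(pi: MisclassMatrix, lam: float) -> SpectralPower:
    """Pi^lam via eigen-decomposition, keeping the decomposition for audit."""
    if lam < -1:
        raise ValueError("exponents below -1 are outside the extrapolation range")
    vals, vecs = _spectral(pi)
    if np.any(vals <= 0) and lam != round(lam):
        raise PowerExistenceError(
            "non-positive eigenvalues: fractional powers do not exist "
            f"(eigenvalues {np.sort(vals)})"
        )
    powered = vecs @ np.diag(vals**lam) @ np.linalg.inv(vecs)
    return SpectralPower(vals, vecs, lam, powered)


def matrix_power(pi: MisclassMatrix, lam: float) -> MisclassMatrix:
    """Pi^lam as a misclassification matrix.

    Entries in (-1e-10, 0) arising from numerical round-off are clipped to 0
    and columns renormalized; genuinely negative entries raise, since the
    power then fails to be a probability matrix.
    """
    if lam == 0:
        return MisclassMatrix(np.eye(pi.m))
    if lam == 1:
        return MisclassMatrix(pi.matrix.copy())
    P = spectral_power(pi, lam).matrix
    if lam >= 0:
        if np.any(P < -_IMAG_TOL):
            raise PowerExistenceError(
                f"Pi^{lam} has negative entries (min {P.min():.3g}): "
                "not a misclassification matrix"
            )
        P = np.clip(P, 0.0, None)
        P = P / P.sum(axis=0, keepdims=True)
        return MisclassMatrix(P)
    return MisclassMatrix(P, validate=False)


@dataclass(frozen=True)
class ExistenceReport:
    """Diagnostic for whether Pi^lambda exists on a lambda range."""

    ok: bool
    eigenvalues: np.ndarray
    eigenvalues_real_positive: bool
    min_entry: float
    lam_grid: np.ndarray
    reasons: list[str] = field(default_factory=list)


def check_existence(pi: MisclassMatrix, lam_max: float = 3.0, n_grid: int = 121) -> ExistenceReport:
    """Check the spectral-power existence conditions on lambda in [0, lam_max]."""
    reasons: list[str] = []
    grid = np.linspace(0.0, lam_max, n_grid)
    try:
        vals, vecs = _spectral(pi)
    except PowerExistenceError as exc:
        vals = np.linalg.eigvals(pi.matrix)
        return ExistenceReport(False, vals, False, np.nan, grid, [str(exc)])
    real_pos = bool(np.all(vals > 0))
    if not real_pos:
        reasons.append(f"eigenvalues not strictly positive: {np.sort(vals)}")
        return ExistenceReport(False, vals, False, np.nan, grid, reasons)
    inv = np.linalg.inv(vecs)
    min_entry = np.inf
    for lam in grid:
        P = vecs @ np.diag(vals**lam) @ inv
        min_entry = min(min_entry, float(P.min()))
    if min_entry < -_IMAG_TOL:
        reasons.append(f"Pi^lambda develops negative entries (min {min_entry:.3g})")
    return ExistenceReport(not reasons, vals, True, min_entry, grid, reasons)


def _classify(assignment: ClusterAssignment, X: np.ndarray) -> np.ndarray:
    """Apply the fitted classification rule to new points: maximum posterior
    for a GMM, nearest center for the distance-based algorithms."""
    if assignment.method == "gmm":
        post = posterior_from_mixture(assignment.mixture, X)
        return np.argmax(post, axis=1) + 1
    if assignment.centers is None:
        raise ValueError("fitted model lacks centers for classification")
    d2 = ((X[:, None, :] - assignment.centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1


def estimate_from_fitted_clustering(
    assignment: ClusterAssignment,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> MisclassMatrix:
    """Parametric Monte-Carlo estimate of Pi from a fitted clustering model.

    For each class j, draw ``n_mc`` points from the fitted class-j Gaussian
    (mixture component for a GMM, per-cluster empirical Gaussian for k-means),
    classify them with the fitted rule, and set pi_ij to the fraction assigned
    to class i. Columns sum to one by construction.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be a positive number of draws per class")
    if assignment.mixture is None:
        raise ValueError("assignment carries no fitted model to simulate from")
    mix = assignment.mixture
    rng = np.random.default_rng(seed)
    m = mix.n_classes
    cols = []
    for j in range(m):
        X = rng.multivariate_normal(mix.means[j], mix.covariances[j], size=n_mc,
                                    method="cholesky")
        pred = _classify(assignment, X)
        cols.append(np.bincount(pred - 1, minlength=m) / n_mc)
    return MisclassMatrix(np.column_stack(cols))


@dataclass(frozen=True)
class OutOfBagResult:
    """All per-replicate out-of-bag matrices plus their element-wise mean."""

    matrices: list[MisclassMatrix]
    average: MisclassMatrix


def estimate_out_of_bag(
    features: np.ndarray,
    reference_labels: np.ndarray,
    n_boot: int = 100,
    m: int = 2,
    seed: int | None = None,
    fit=fit_gmm,
) -> OutOfBagResult:
    """Bootstrap out-of-bag estimate of Pi against a reference labelling.

    Per replicate: resample rows with replacement, fit the clustering on the
    in-bag rows, align it to the reference labels (in-bag), classify the
    out-of-bag rows, and column-normalize the out-of-bag confusion matrix
    against the reference. A column with no out-of-bag members is imputed from
    the average of the other replicates, with a warning.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    ref = np.asarray(reference_labels, dtype=int)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    raw: list[np.ndarray] = []
    missing: list[tuple[int, int]] = []  # (replicate, column)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        assignment = fit(X[idx], m, seed=rng.integers(2**31 - 1))
        assignment = align_labels(assignment, ref[idx])
        pred = _classify(assignment, X[oob])
        conf = np.zeros((m, m))
        for i in range(1, m + 1):
            for j in range(1, m + 1):
                conf[i - 1, j - 1] = np.sum((pred == i) & (ref[oob] == j))
        sums = conf.sum(axis=0)
        P = np.zeros_like(conf)
        for j in range(m):
            if sums[j] == 0:
                missing.append((b, j))
                P[:, j] = np.nan
            else:
                P[:, j] = conf[:, j] / sums[j]
        raw.append(P)
    stacked = np.stack(raw)
    if missing:
        warnings.warn(
            f"{len(missing)} out-of-bag class column(s) had no members; "
            "imputed from the average over the remaining replicates",
            RuntimeWarning,
        )
        col_means = np.nanmean(stacked, axis=0)
        for b, j in missing:
            stacked[b, :, j] = col_means[:, j]
    matrices = [MisclassMatrix(P) for P in stacked]
    return OutOfBagResult(matrices, MisclassMatrix(stacked.mean(axis=0)))
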