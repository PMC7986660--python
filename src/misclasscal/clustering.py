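"""Unsupervised clustering front-ends used by the correction methods.

Three procedures are exposed with a common return type: a Gaussian mixture
fitted by EM (scikit-learn), Lloyd's k-means (scikit-learn), and fuzzy
c-means (implemented here). Each returns hard 1-based labels, a row-stochastic
posterior/membership matrix, and the fitted parameters needed downstream to
estimate the misclassification matrix.

Cluster indices from any unsupervised fit are arbitrary; ``align_labels``
resolves label switching against a reference labelling by maximum-agreement
assignment so that class 1 of the clustering means class 1 of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal
from sklearn.cluster import KMeans, kmeans_plusplus
from sklearn.mixture import GaussianMixture

from .synthetic_data import MixtureModel

__all__ = [
    "ClusterAssignment",
    "ConvergenceError",
    "fit_gmm",
    "fit_kmeans",
    "fit_fuzzy_cmeans",
    "align_labels",
    "posterior_from_mixture",
]


class ConvergenceError(RuntimeError):
    """An iterative clustering fit failed to converge."""


@dataclass(frozen=True)
class ClusterAssignment:
    """Output of a clustering fit.

    Fields
    ------
    hard_labels : (n,) 1-based cluster labels, the argmax of each posterior row
        (ties broken toward the lowest index).
    posterior : (n, m) row-stochastic matrix of posterior class probabilities
        (GMM responsibilities, fuzzy memberships, or one-hot rows for k-means).
    method : which algorithm produced the fit.
    mixture : fitted class-conditional Gaussians (priors, means, covariances).
        For k-means / fuzzy c-means these are the per-cluster empirical
        moments, which the misclassification estimator samples from.
    centers : cluster centers for distance-based classification rules
        (k-means, fuzzy c-means); None for GMM.
    """

    hard_labels: np.ndarray
    posterior: np.ndarray
    method: Literal["gmm", "kmeans", "fcm"]
    mixture: MixtureModel | None = None
    centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "hard_labels", np.asarray(self.hard_labels, dtype=int))
        object.__setattr__(self, "posterior", np.asarray(self.posterior, dtype=float))
        n, m = self.posterior.shape
        if m < 2:
            raise ValueError("need at least two clusters")
        if self.hard_labels.shape != (n,):
            raise ValueError("labels/posterior lengths disagree")
        if not np.allclose(self.posterior.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("posterior rows must sum to 1")
        if not np.array_equal(self.hard_labels, np.argmax(self.posterior, axis=1) + 1):
            raise ValueError("hard labels must be the argmax of the posterior rows")

    @property
    def n_clusters(self) -> int:
        return self.posterior.shape[1]


def _validate_features(features: np.ndarray, m: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if m < 2:
        raise ValueError("need at least two clusters to define a class effect")
    if X.shape[0] <= m:
        raise ValueError("need more observations than clusters")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.allclose(X, X[0]):
        raise ValueError("all feature rows identical: clustering is degenerate")
    return X


def _empirical_mixture(X: np.ndarray, labels: np.ndarray, m: int) -> MixtureModel:
    """Per-cluster empirical proportions, means and covariances (ridge-regularized
    so tiny clusters still yield a valid Gaussian)."""
    priors = np.array([(labels == h).mean() for h in range(1, m + 1)])
    means, covs = [], []
    for h in range(1, m + 1):
        sub = X[labels == h]
        if sub.shape[0] == 0:  # empty cluster: fall back to global moments
            sub = X
        means.append(sub.mean(axis=0))
        cov = np.cov(sub, rowvar=False) if sub.shape[0] > 1 else np.eye(X.shape[1])
        covs.append(np.atleast_2d(cov) + 1e-8 * np.eye(X.shape[1]))
    return MixtureModel(priors=priors, means=np.vstack(means), covariances=np.stack(covs))


def _full_covariances(gm: GaussianMixture, p: int) -> np.ndarray:
    """Expand scikit-learn's packed covariance storage to (m, p, p)."""
    m = gm.n_components
    c = gm.covariances_
    if gm.covariance_type == "full":
        return c
    if gm.covariance_type == "tied":
        return np.broadcast_to(c, (m, p, p)).copy()
    if gm.covariance_type == "diag":
        return np.stack([np.diag(row) for row in c])
    return np.stack([v * np.eye(p) for v in c])  # spherical


def fit_gmm(
    features: np.ndarray,
    m: int = 2,
    seed: int | None = None,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-4,
    covariance_type: str = "auto",
) -> ClusterAssignment:
    """EM fit of an m-component Gaussian mixture; posterior = responsibilities.

    k-means++ initialization with ``n_init`` restarts, best log-likelihood
    kept. ``covariance_type="auto"`` fits the four scikit-learn covariance
    structures (full, tied, diag, spherical) and keeps the lowest BIC — the
    standard model-based-clustering recipe, which avoids overparameterizing
    the class boundary when a constrained structure fits as well.
    """
    X = _validate_features(features, m)
    candidates = (
        ("full", "tied", "diag", "spherical")
        if covariance_type == "auto"
        else (covariance_type,)
    )
    rs = np.random.default_rng(seed).integers(2**31 - 1)
    best = None
    for ct in candidates:
        gm = GaussianMixture(
            n_components=m,
            covariance_type=ct,
            n_init=n_init,
            init_params="k-means++",
            max_iter=max_iter,
            tol=tol,
            reg_covar=1e-6,
            random_state=rs,
        ).fit(X)
        bic = gm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, gm)
    gm = best[1]
    if not gm.converged_:
        raise ConvergenceError(f"EM did not converge within {gm.n_iter_} iterations")
    post = gm.predict_proba(X)
    labels = np.argmax(post, axis=1) + 1
    mixture = MixtureModel(
        priors=gm.weights_,
        means=gm.means_,
        covariances=_full_covariances(gm, X.shape[1]),
    )
    return ClusterAssignment(labels, post, "gmm", mixture=mixture)


def fit_kmeans(
    features: np.ndarray,
    m: int = 2,
    seed: int | None = None,
    n_init: int = 10,
) -> ClusterAssignment:
    """Lloyd's k-means with k-means++ init and ``n_init`` restarts.

    The posterior matrix is one-hot (hard algorithm). The fitted model carries
    cluster centers plus per-cluster empirical proportions, means and
    covariances, which the misclassification-matrix estimator needs.
    """
    X = _validate_features(features, m)
    km = KMeans(
        n_clusters=m,
        n_init=n_init,
        random_state=np.random.default_rng(seed).integers(2**31 - 1),
    ).fit(X)
    labels = km.labels_ + 1
    post = np.zeros((X.shape[0], m))
    post[np.arange(X.shape[0]), labels - 1] = 1.0
    return ClusterAssignment(
        labels, post, "kmeans",
        mixture=_empirical_mixture(X, labels, m),
        centers=km.cluster_centers_.copy(),
    )


def fit_fuzzy_cmeans(
    features: np.ndarray,
    m: int = 2,
    fuzzifier: float = 2.0,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> ClusterAssignment:
    """Fuzzy c-means: soft memberships u_ih minimizing sum u^f ||x - c||^2.

    Memberships play the role of posterior class probabilities for regression
    calibration when the clustering itself is distance-based.
    """
    X = _validate_features(features, m)
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must exceed 1")
    rng = np.random.default_rng(seed)
    centers, _ = kmeans_plusplus(X, m, random_state=rng.integers(2**31 - 1))
    u_prev = None
    for it in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (fuzzifier - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        uf = u**fuzzifier
        centers = (uf.T @ X) / uf.sum(axis=0)[:, None]
        if u_prev is not None and np.abs(u - u_prev).max() < tol:
            break
        u_prev = u
    else:
        raise ConvergenceError(f"fuzzy c-means did not converge in {max_iter} iterations")
    labels = np.argmax(u, axis=1) + 1
    return ClusterAssignment(
        labels, u, "fcm",
        mixture=_empirical_mixture(X, labels, m),
        centers=centers,
    )


def align_labels(assignment: ClusterAssignment, reference_labels: np.ndarray) -> ClusterAssignment:
    """Permute cluster identities to best match a reference labelling.

    Solves the optimal assignment on the confusion matrix (maximizing total
    agreement), then applies the permutation jointly to hard labels, posterior
    columns and fitted-model components. Idempotent: aligning twice with the
    same reference is a no-op.
    """
    ref = np.asarray(reference_labels, dtype=int)
    m = assignment.n_clusters
    if ref.shape != assignment.hard_labels.shape:
        raise ValueError("reference labels length mismatch")
    if ref.min() < 1 or ref.max() > m:
        raise ValueError("reference labels exceed the number of clusters")
    conf = np.zeros((m, m))
    for i in range(1, m + 1):
        for j in range(1, m + 1):
            conf[i - 1, j - 1] = np.sum((ref == i) & (assignment.hard_labels == j))
    rows, cols = linear_sum_assignment(-conf)
    # perm[old_cluster] = new (reference-aligned) cluster, both 0-based
    perm = np.empty(m, dtype=int)
    perm[cols] = rows
    inv = np.argsort(perm)  # new column k comes from old column inv[k]
    new_post = assignment.posterior[:, inv]
    new_labels = np.argmax(new_post, axis=1) + 1
    mixture = assignment.mixture
    if mixture is not None:
        mixture = MixtureModel(
            priors=mixture.priors[inv],
            means=mixture.means[inv],
            covariances=mixture.covariances[inv],
        )
    centers = assignment.centers[inv] if assignment.centers is not None else None
    return ClusterAssignment(new_labels, new_post, assignment.method,
                             mixture=mixture, centers=centers)


def posterior_from_mixture(mixture: MixtureModel, X: np.ndarray) -> np.ndarray:
    """Bayes-rule posterior P(H=h | Z=z) under a fitted Gaussian mixture."""
    dens = np.column_stack([
        mixture.priors[h] * multivariate_normal.pdf(X, mixture.means[h], mixture.covariances[h])
        for h in range(mixture.n_classes)
    ])
    return dens / dens.sum(axis=1, keepdims=True)
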