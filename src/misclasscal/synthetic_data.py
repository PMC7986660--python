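"""Simulation inputs for the misclassification study.

Generates the ingredients of the two-stage workflow this package corrects:
features drawn from a finite Gaussian mixture with known latent classes, a
binary outcome that depends on the *true* class through a logistic model with
treatment contrasts, and right-censored survival outcomes with class-dependent
exponential event times.

All generators accept either an integer seed or a ``numpy.random.Generator``
and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "MixtureModel",
    "RegressionTruth",
    "SimulatedDataset",
    "two_class_mixture",
    "sample_mixture",
    "attach_logistic_outcome",
    "attach_survival_outcome",
    "noisy_binary_labels",
    "linear_predictor",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MixtureModel:
    """A finite Gaussian mixture: class priors, component means and covariances.

    Parameters
    ----------
    priors : (m,) probability vector, one entry per latent class.
    means : (m, p) component means.
    covariances : (m, p, p) symmetric positive-definite component covariances.
    """

    priors: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "priors", np.asarray(self.priors, dtype=float))
        object.__setattr__(self, "means", np.atleast_2d(np.asarray(self.means, dtype=float)))
        object.__setattr__(self, "covariances", np.asarray(self.covariances, dtype=float))
        m = self.priors.shape[0]
        if m < 2:
            raise ValueError("a mixture needs at least two classes")
        if np.any(self.priors < 0) or np.any(self.priors > 1) or abs(self.priors.sum() - 1) > 1e-8:
            raise ValueError("priors must be probabilities summing to 1")
        p = self.means.shape[1]
        if self.means.shape != (m, p) or self.covariances.shape != (m, p, p):
            raise ValueError("means/covariances shapes inconsistent with priors")
        for j, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance of component {j + 1} is not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"covariance of component {j + 1} is not positive definite")

    @property
    def n_classes(self) -> int:
        return self.priors.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def two_class_mixture(prior_class1: float = 0.5, separation: float = 1.0) -> MixtureModel:
    """The study's two-class bivariate mixture: means (-s, 0) and (s, 0),
    identity covariances, class-1 prior ``prior_class1``.
    """
    return MixtureModel(
        priors=np.array([prior_class1, 1.0 - prior_class1]),
        means=np.array([[-separation, 0.0], [separation, 0.0]]),
        covariances=np.stack([np.eye(2), np.eye(2)]),
    )


@dataclass(frozen=True)
class RegressionTruth:
    """True coefficients on the linear-predictor scale.

    For ``logistic`` the vector is (intercept, effect of class 2, ..., effect
    of class m) under treatment contrasts; for ``cox`` it is the m-1 log-hazard
    ratios of classes 2..m versus class 1.
    """

    coefficients: np.ndarray
    model_kind: Literal["logistic", "cox"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))
        if self.model_kind not in ("logistic", "cox"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.coefficients.ndim != 1 or self.coefficients.size < 1:
            raise ValueError("coefficients must be a non-empty vector")

    @property
    def n_classes(self) -> int:
        k = self.coefficients.size
        return k if self.model_kind == "logistic" else k + 1


def linear_predictor(labels: np.ndarray, truth: RegressionTruth) -> np.ndarray:
    """x_h^T beta under treatment contrasts, for 1-based hard labels."""
    labels = np.asarray(labels)
    beta = truth.coefficients
    m = truth.n_classes
    if labels.min() < 1 or labels.max() > m:
        raise ValueError(f"labels must lie in 1..{m}")
    if truth.model_kind == "logistic":
        eta = np.full(labels.shape, beta[0])
        for h in range(2, m + 1):
            eta = eta + beta[h - 1] * (labels == h)
    else:
        eta = np.zeros(labels.shape, dtype=float)
        for h in range(2, m + 1):
            eta = eta + beta[h - 2] * (labels == h)
    return eta


@dataclass(frozen=True)
class SimulatedDataset:
    """Features, true class labels and (optionally) an outcome.

    ``true_labels`` are 1-based. Exactly one outcome may be present: a binary
    vector ``y``, or the right-censored pair ``(time, event)``.
    """

    features: np.ndarray
    true_labels: np.ndarray
    y: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.atleast_2d(np.asarray(self.features, dtype=float)))
        object.__setattr__(self, "true_labels", np.asarray(self.true_labels, dtype=int))
        n = self.features.shape[0]
        if self.true_labels.shape != (n,):
            raise ValueError("features and labels lengths disagree")
        if self.true_labels.min() < 1:
            raise ValueError("labels are 1-based")
        if self.y is not None:
            y = np.asarray(self.y, dtype=int)
            if y.shape != (n,) or set(np.unique(y)) - {0, 1}:
                raise ValueError("binary outcome must be 0/1 of length n")
            object.__setattr__(self, "y", y)
        if (self.time is None) != (self.event is None):
            raise ValueError("survival outcome needs both time and event")
        if self.time is not None:
            t = np.asarray(self.time, dtype=float)
            e = np.asarray(self.event, dtype=int)
            if t.shape != (n,) or e.shape != (n,):
                raise ValueError("survival outcome length disagrees with features")
            if np.any(t <= 0):
                raise ValueError("survival times must be strictly positive")
            if set(np.unique(e)) - {0, 1}:
                raise ValueError("event indicator must be 0/1")
            object.__setattr__(self, "time", t)
            object.__setattr__(self, "event", e)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def outcome(self):
        """The outcome in the form the fitters expect."""
        if self.y is not None:
            return self.y
        if self.time is not None:
            return (self.time, self.event)
        raise ValueError("dataset has no outcome attached")

    def to_frame(self) -> pd.DataFrame:
        cols = {f"z{j + 1}": self.features[:, j] for j in range(self.features.shape[1])}
        cols["true_class"] = self.true_labels
        if self.y is not None:
            cols["y"] = self.y
        if self.time is not None:
            cols["time"] = self.time
            cols["status"] = self.event
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_mixture(model: MixtureModel, n: int, seed=None) -> SimulatedDataset:
    """Draw n observations: a latent class from the priors, then features from
    that class's Gaussian component."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = _rng(seed)
    labels = rng.choice(model.n_classes, size=n, p=model.priors) + 1
    chol = np.linalg.cholesky(model.covariances)  # (m, p, p)
    z = rng.standard_normal((n, model.n_features))
    feats = model.means[labels - 1] + np.einsum("nij,nj->ni", chol[labels - 1], z)
    return SimulatedDataset(features=feats, true_labels=labels)


def attach_logistic_outcome(
    data: SimulatedDataset, truth: RegressionTruth, seed=None
) -> SimulatedDataset:
    """Bernoulli outcome with success probability expit(x_h^T beta) in the
    TRUE class h."""
    if truth.model_kind != "logistic":
        raise ValueError("truth must be a logistic model")
    rng = _rng(seed)
    p = expit(linear_predictor(data.true_labels, truth))
    y = (rng.random(data.n) < p).astype(int)
    return replace(data, y=y, time=None, event=None)


def attach_survival_outcome(
    data: SimulatedDataset, censor_rate: float = 0.5, seed=None
) -> SimulatedDataset:
    """Exponential event times with rate equal to the numeric class label
    (classes 1 and 2, hence true hazard ratio 2), independently censored by
    an Exponential(censor_rate) time."""
    if censor_rate <= 0:
        raise ValueError("censor_rate must be positive")
    if set(np.unique(data.true_labels)) - {1, 2}:
        raise ValueError("survival generator is defined for classes {1, 2}")
    rng = _rng(seed)
    t_event = rng.exponential(1.0 / data.true_labels.astype(float))
    t_cens = rng.exponential(1.0 / censor_rate, size=data.n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return replace(data, y=None, time=time, event=event)


def noisy_binary_labels(
    n: int,
    misclass_prob: float,
    beta: np.ndarray | tuple = (-1.0, 2.0),
    seed=None,
):
    """Binary labels with symmetric label noise, plus a logistic outcome.

    True labels are Bernoulli(0.5) coded 1/2; each observed label is flipped
    independently with probability ``misclass_prob``; the outcome is logistic
    in the TRUE label with coefficients ``beta`` (intercept, class-2 effect on
    the log-odds scale).

    Returns ``(true_labels, corrupted_labels, y)``.
    """
    if not 0 <= misclass_prob < 0.5:
        raise ValueError("misclass_prob must lie in [0, 0.5): at 0.5 the true "
                         "class is no longer identifiable from the noisy label")
    rng = _rng(seed)
    true = rng.integers(0, 2, size=n) + 1
    flip = rng.random(n) < misclass_prob
    corrupted = np.where(flip, 3 - true, true)
    truth = RegressionTruth(np.asarray(beta, dtype=float), "logistic")
    p = expit(linear_predictor(true, truth))
    y = (rng.random(n) < p).astype(int)
    return true, corrupted, y
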