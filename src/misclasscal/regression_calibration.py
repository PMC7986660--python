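"""Regression calibration: posterior class probabilities as soft indicators.

Instead of the hard class indicators, the design matrix carries the posterior
probability of each non-reference class given the features — the conditional
expectation of the indicator given the observed data. The outcome model is
then fitted unchanged. With degenerate 0/1 posteriors this reduces exactly to
the naive fit.

Wald standard errors are reported as-is: no inflation for the uncertainty in
the estimated posteriors. When posteriors concentrate near 0/1 the method
therefore behaves, for better and worse, much like the naive estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fitters import ModelFit, ModelSpec, fit_model
from .clustering import ClusterAssignment

__all__ = ["CalibratedDesign", "build_calibrated_design", "fit_rc"]


@dataclass(frozen=True)
class CalibratedDesign:
    """Treatment-contrast design with posterior probabilities for classes 2..m
    (plus an intercept column for logistic models)."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", M)
        probs = M[:, 1:] if self.names and self.names[0] == "beta1" else M
        if np.any(probs < -1e-10) or np.any(probs > 1 + 1e-10):
            raise ValueError("probability columns must lie in [0, 1]")


def build_calibrated_design(assignment: ClusterAssignment, spec: ModelSpec) -> CalibratedDesign:
    """Replace the class-2..m indicators with posterior probabilities."""
    post = assignment.posterior
    if post is None:
        raise ValueError(
            "clustering provides no posterior probabilities; use a GMM or "
            "fuzzy c-means to obtain soft class memberships for calibration"
        )
    if assignment.n_clusters != spec.n_classes:
        raise ValueError("cluster count disagrees with the model's class count")
    if not np.allclose(post.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    cols = [post[:, h - 1] for h in range(2, spec.n_classes + 1)]
    if spec.kind == "logistic":
        cols.insert(0, np.ones(post.shape[0]))
    return CalibratedDesign(np.column_stack(cols), spec.coef_names)


def fit_rc(outcome, assignment: ClusterAssignment, spec: ModelSpec) -> ModelFit:
    """Fit the outcome model on the calibrated (soft-indicator) design.

    Bit-identical to the naive fit when the posteriors are one-hot.
    """
    design = build_calibrated_design(assignment, spec)
    return fit_model(outcome, design.matrix, spec)
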