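"""Low-level regression fitters shared by the naive, RC and MCSIMEX paths.

Logistic regression is delegated to statsmodels. The Cox partial-likelihood
fitter is implemented here directly as a vectorized Newton solver with Efron
tie handling: the simulation-extrapolation and bootstrap machinery refit the
outcome model tens of thousands of times, so per-fit overhead dominates the
cost of a study run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "FitError",
    "ModelSpec",
    "ModelFit",
    "indicator_design",
    "fit_logistic",
    "fit_cox",
    "fit_model",
]

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


class FitError(RuntimeError):
    """A regression fit failed (separation, singular information, no events...)."""


@dataclass(frozen=True)
class ModelSpec:
    """Outcome-model contract: which regression and how many latent classes.

    The design always uses treatment contrasts with class 1 as reference:
    logistic gets an intercept plus indicators for classes 2..m, Cox gets the
    m-1 indicators only (the baseline hazard absorbs the reference level).
    """

    kind: Literal["logistic", "cox"]
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("logistic", "cox"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes to define a class effect")

    @property
    def coef_names(self) -> list[str]:
        if self.kind == "logistic":
            return ["beta1"] + [f"beta{h}" for h in range(2, self.n_classes + 1)]
        return [f"beta{h}" for h in range(2, self.n_classes + 1)]

    @property
    def n_coef(self) -> int:
        return self.n_classes if self.kind == "logistic" else self.n_classes - 1


@dataclass
class ModelFit:
    """Point estimates with Wald inference from a single regression fit."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    ci_95: np.ndarray  # (k, 2) lower/upper
    loglik: float
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        self.ci_95 = np.asarray(self.ci_95, dtype=float)
        k = self.coefficients.shape[0]
        if self.standard_errors.shape != (k,) or self.ci_95.shape != (k, 2):
            raise ValueError("coefficient / SE / CI shapes disagree")
        inside = (self.ci_95[:, 0] <= self.coefficients) & (
            self.coefficients <= self.ci_95[:, 1]
        )
        if not np.all(inside | ~np.isfinite(self.ci_95).all(axis=1)):
            raise ValueError("confidence intervals must contain the point estimates")

    def covers(self, truth: Sequence[float]) -> np.ndarray:
        """Elementwise: does each 95% CI contain the corresponding true value?"""
        t = np.asarray(truth, dtype=float)
        return (self.ci_95[:, 0] <= t) & (t <= self.ci_95[:, 1])


def indicator_design(labels: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Treatment-contrast design matrix from hard 1-based class labels."""
    labels = np.asarray(labels)
    m = spec.n_classes
    if labels.min() < 1 or labels.max() > m:
        raise ValueError(f"labels must lie in 1..{m}")
    cols = [np.asarray(labels == h, dtype=float) for h in range(2, m + 1)]
    if spec.kind == "logistic":
        cols.insert(0, np.ones(labels.shape[0]))
    return np.column_stack(cols)


def _wald(coef: np.ndarray, se: np.ndarray, loglik: float, names: list[str]) -> ModelFit:
    ci = np.column_stack([coef - _Z95 * se, coef + _Z95 * se])
    return ModelFit(coef, se, ci, float(loglik), names)


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> ModelFit:
    """Maximum-likelihood logistic regression with Wald 95% CIs."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logistic outcome must be binary 0/1")
    names = names or [f"x{j}" for j in range(X.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge (possible separation)")
    se = np.asarray(res.bse)
    if not np.all(np.isfinite(se)) or np.any(se > 1e3):
        raise FitError("logistic fit degenerate: non-finite or exploding standard errors")
    return _wald(np.asarray(res.params), se, res.llf, names)


def _efron_loglik_grad_hess(beta, times, events, X):
    """Efron-approximated Cox partial log-likelihood with gradient and Hessian.

    Inputs must be sorted by time ascending. Fully vectorized: one term per
    event, with risk-set sums from reverse cumulative sums and the Efron tie
    correction expressed through per-event tie fractions. Without ties this
    coincides with the exact (Breslow) partial likelihood.
    """
    n, k = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; shifts cancel in the PL ratios
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # risk-set sums over {j : t_j >= t_i} via reverse cumulative sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    # distinct-time groups (times sorted ascending)
    starts = np.flatnonzero(np.r_[True, times[1:] != times[:-1]])
    grp_of_row = np.cumsum(np.r_[True, times[1:] != times[:-1]]) - 1
    ev = np.flatnonzero(events == 1)
    grp = grp_of_row[ev]
    d_g = np.bincount(grp, minlength=starts.size)  # events per distinct time
    # tied-event sums per group
    t0 = np.bincount(grp, weights=w[ev], minlength=starts.size)
    t1 = np.zeros((starts.size, k))
    t2 = np.zeros((starts.size, k, k))
    for j in range(k):
        t1[:, j] = np.bincount(grp, weights=wx[ev, j], minlength=starts.size)
        for l in range(k):
            t2[:, j, l] = np.bincount(grp, weights=wxx[ev, j, l], minlength=starts.size)
    # Efron fraction l/d for the l-th of d tied events at the same time
    within = np.arange(ev.size) - np.r_[0, np.cumsum(d_g)][:-1][grp]
    frac = within / d_g[grp]

    s = starts[grp]
    den = S0[s] - frac * t0[grp]
    num1 = S1[s] - frac[:, None] * t1[grp]
    num2 = S2[s] - frac[:, None, None] * t2[grp]

    ll = eta[ev].sum() - np.log(den).sum()
    g = num1 / den[:, None]
    grad = X[ev].sum(axis=0) - g.sum(axis=0)
    hess = -(num2 / den[:, None, None]).sum(axis=0) + g.T @ g
    return ll, grad, hess


def fit_cox(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> ModelFit:
    """Cox proportional-hazards fit by Newton-Raphson on the partial likelihood.

    Ties are handled by Efron's approximation. Standard errors come from the
    inverse observed information at the optimum.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D")
    n, k = X.shape
    if time.shape != (n,) or event.shape != (n,):
        raise ValueError("time/event/design lengths disagree")
    if np.any(time <= 0):
        raise ValueError("survival times must be strictly positive")
    if event.sum() == 0:
        raise FitError("no events observed; Cox partial likelihood is flat")
    names = names or [f"x{j}" for j in range(k)]

    order = np.argsort(time, kind="stable")
    t, d, Xs = time[order], event[order], X[order]
    # a covariate constant over all events gives a flat likelihood
    if np.any(Xs[d == 1].std(axis=0) == 0) and np.any(Xs.std(axis=0) == 0):
        raise FitError("constant covariate: class effect not identifiable")

    beta = np.zeros(k)
    ll, grad, hess = _efron_loglik_grad_hess(beta, t, d, Xs)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from exc
        # Newton with step halving
        new_beta = beta - step
        for _ in range(30):
            new_ll, new_grad, new_hess = _efron_loglik_grad_hess(new_beta, t, d, Xs)
            if new_ll >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2
        improved = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(grad)) < tol or abs(improved) < 1e-13:
            break
    else:
        raise FitError(f"Cox fit did not converge in {max_iter} iterations")
    if np.abs(beta).max() > 50:
        raise FitError("Cox fit diverged (monotone likelihood / separation)")

    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information at optimum: {exc}") from exc
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)):
        raise FitError("non-finite Cox standard errors")
    return _wald(beta, se, ll, names)


def fit_model(outcome, X: np.ndarray, spec: ModelSpec, names: list[str] | None = None) -> ModelFit:
    """Dispatch on the model kind.

    ``outcome`` is a binary vector for logistic, or a ``(time, event)`` pair
    for Cox.
    """
    names = names or spec.coef_names
    if spec.kind == "logistic":
        return fit_logistic(np.asarray(outcome), X, names)
    time, event = outcome
    return fit_cox(time, event, X, names)
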