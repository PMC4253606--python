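"""The parametric likelihood-ratio (LR) method.

Logistic regression of the disease label on the test value x gives a linear
predictor a0 + a1*x. Because the fit absorbs the pre-test odds of the sample,
the log likelihood-ratio function is the predictor with the log pre-test odds
subtracted:

    log LR(x) = a0 + a1*x - log[P(D) / (1 - P(D))]

The optimal cut-off is the test value where LR(x) = 1 — the point at which a
test result leaves the disease probability unchanged:

    x* = (log[P(D)/(1-P(D))] - a0) / a1

Post-test probabilities for any target pre-test probability follow from
Bayes' theorem in odds form, post-odds = pre-odds * LR(x), which makes the
fitted LR function transferable to populations with a different prevalence.

Fitting is plain maximum likelihood by Newton iterations with step halving.
Under quasi-complete separation (nearly disjoint class supports, as in a
strongly separated scenario) the coefficients drift toward infinity; the fit
then stops at the iteration cap and is returned flagged as non-converged
rather than raising, so downstream summaries can include and count it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .cutoff_methods import DiagnosticDataset

__all__ = [
    "LogisticFit",
    "PostTestCurve",
    "NonIdentifiableError",
    "InvertedPredictorError",
    "fit_logistic",
    "lr_cutoff",
    "post_test_probability",
    "export_post_test_curve",
]

MAX_ITER = 50
TOL_LOGLIK = 1e-10
TOL_GRADIENT = 1e-8


class NonIdentifiableError(ValueError):
    """The logistic model cannot be fitted (single-class data, too few rows)."""


class InvertedPredictorError(ValueError):
    """The fitted slope is not positive, so LR(x) = 1 has no usable root."""


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic-regression estimates for one dataset.

    ``alpha0_corrected = alpha0 - log(p/(1-p))`` with ``p = p_d_fit``, the
    empirical disease fraction of the fitted data; the corrected predictor
    ``alpha0_corrected + alpha1*x`` equals log LR(x).
    """

    alpha0: float
    alpha1: float
    alpha0_corrected: float
    p_d_fit: float
    converged: bool
    n_iter: int

    def log_lr(self, x) -> np.ndarray | float:
        """log LR(x) = alpha0_corrected + alpha1 * x."""
        return self.alpha0_corrected + self.alpha1 * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class PostTestCurve:
    """A fitted LR function applied at a target pre-test probability."""

    fit: LogisticFit
    p_d_applied: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_d_applied < 1.0:
            raise ValueError("p_d_applied must be strictly between 0 and 1")


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # ll = sum(y*eta - log(1 + exp(eta))), computed overflow-safely
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    data: DiagnosticDataset,
    *,
    max_iter: int = MAX_ITER,
    tol_loglik: float = TOL_LOGLIK,
    tol_gradient: float = TOL_GRADIENT,
) -> LogisticFit:
    """Fit label ~ logistic(alpha0 + alpha1 * x) by maximum likelihood.

    Newton iterations with step halving; convergence is declared when the
    log-likelihood improvement drops below ``tol_loglik`` or the gradient norm
    below ``tol_gradient``. On separation the fit runs to ``max_iter`` and is
    returned with ``converged=False`` (never an exception).

    Raises
    ------
    NonIdentifiableError
        If only one class is present or there are fewer than 3 observations.
    """
    x = data.values
    y = data.labels.astype(float)
    if len(data) < 3:
        raise NonIdentifiableError("need at least 3 observations")
    if not data.both_classes_present:
        raise NonIdentifiableError("both classes must be present to fit")

    p_bar = y.mean()
    beta = np.array([np.log(p_bar / (1.0 - p_bar)), 0.0])
    eta = beta[0] + beta[1] * x
    loglik = _loglik(eta, y)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = expit(eta)
        resid = y - p
        grad = np.array([resid.sum(), resid @ x])
        if np.hypot(*grad) < tol_gradient:
            converged = True
            n_iter -= 1
            break
        w = p * (1.0 - p)
        sw, swx, swxx = w.sum(), w @ x, w @ (x * x)
        det = sw * swxx - swx * swx
        if not np.isfinite(det) or det <= 0:
            break  # Hessian numerically singular (deep separation)
        step = np.array(
            [(swxx * grad[0] - swx * grad[1]) / det, (sw * grad[1] - swx * grad[0]) / det]
        )
        # step-halving to guarantee likelihood ascent
        new_loglik = -np.inf
        for _ in range(30):
            trial = beta + step
            eta_trial = trial[0] + trial[1] * x
            new_loglik = _loglik(eta_trial, y)
            if np.isfinite(new_loglik) and new_loglik >= loglik - 1e-14:
                break
            step = step / 2.0
        else:
            break
        beta = beta + step
        eta = beta[0] + beta[1] * x
        if abs(new_loglik - loglik) < tol_loglik:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    pre_odds = p_bar / (1.0 - p_bar)
    return LogisticFit(
        alpha0=float(beta[0]),
        alpha1=float(beta[1]),
        alpha0_corrected=float(beta[0] - np.log(pre_odds)),
        p_d_fit=float(p_bar),
        converged=converged,
        n_iter=n_iter,
    )


def lr_cutoff(fit: LogisticFit) -> float:
    """The test value where LR(x) = 1: x* = -alpha0_corrected / alpha1.

    Raises
    ------
    InvertedPredictorError
        If ``alpha1 <= 0`` (non-informative or inverted predictor).
    """
    if fit.alpha1 <= 0:
        raise InvertedPredictorError(
            f"slope alpha1 = {fit.alpha1:.4g} is not positive; "
            "LR(x) = 1 has no usable root"
        )
    return -fit.alpha0_corrected / fit.alpha1


def post_test_probability(curve: PostTestCurve, x) -> np.ndarray | float:
    """P(D | x) at target prevalence ``curve.p_d_applied``.

    Computed in odds form: post-odds = pre-odds * LR(x), with
    LR(x) = exp(alpha0_corrected + alpha1 * x) from the fitted model.
    Monotone increasing in x whenever alpha1 > 0.
    """
    p = curve.p_d_applied
    log_pre_odds = np.log(p / (1.0 - p))
    # expit of the log post-odds is overflow-safe for any magnitude of LR
    result = expit(log_pre_odds + curve.fit.log_lr(x))
    return float(result) if np.isscalar(x) else result


def export_post_test_curve(
    curve: PostTestCurve,
    path: str | Path,
    *,
    x_min: float,
    x_max: float,
    step: float = 0.1,
) -> None:
    """Write a delimited (x, P(D|x)) table for external plotting."""
    if x_max <= x_min or step <= 0:
        raise ValueError("need x_max > x_min and step > 0")
    xs = np.arange(x_min, x_max + step / 2, step)
    ps = post_test_probability(curve, xs)
    with Path(path).open("w") as handle:
        handle.write("x,post_test_probability\n")
        for xi, pi in zip(xs, ps):
            handle.write(f"{xi:.10g},{pi:.10g}\n")
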