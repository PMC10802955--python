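"""Cox proportional hazards model fitted by Newton ascent of the partial
likelihood, with the Breslow approximation for tied event times and a
Breslow estimator of the baseline cumulative hazard.

The hazard is h(t | x) = h0(t) * exp(x . beta); beta maximises the log
partial likelihood

    l(beta) = sum_{events i} [ eta_i - log sum_{j in R(t_i)} exp(eta_j) ]

where R(t_i) is the risk set of subjects still under observation just
before t_i.  Event times are continuous under the simulator, so ties have
measure zero, but the Breslow treatment keeps the fit well defined after
any rounding of times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datagen import SurvivalDataset, expand_design
from .base import SurvivalPredictor, check_has_events, step_interpolate

__all__ = ["breslow_loglik", "breslow_baseline", "CoxFit", "CoxPHModel"]


def _risk_set_sums(time: np.ndarray, event: np.ndarray, eta: np.ndarray, X: np.ndarray):
    """Per-event risk-set aggregates via reverse cumulative sums.

    Returns, for each event (ascending time order), the risk-set sums of
    w = exp(eta), w*x and w*x x^T, with tied event times sharing one risk
    set (Breslow).
    """
    order = np.argsort(time, kind="stable")
    t, d, e = time[order], event[order], eta[order]
    x = X[order]
    w = np.exp(e)
    # reverse cumulative sums: sums over subjects with time >= t_k
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (x[:, :, None] * x[:, None, :]))[::-1], axis=0)[::-1]
    # first index of each tie group, so tied events share the risk set
    first = np.searchsorted(t, t, side="left")
    ev = np.flatnonzero(d == 1)
    g = first[ev]
    return t[ev], e[ev], x[ev], s0[g], s1[g], s2[g]


def breslow_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    order: int = 2,
):
    """Log partial likelihood and, optionally, its gradient and Hessian."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    _, e_ev, x_ev, s0, s1, s2 = _risk_set_sums(time, event, eta, X)
    ll = float(np.sum(e_ev - np.log(s0)))
    if order == 0:
        return ll
    mean = s1 / s0[:, None]
    grad = np.sum(x_ev - mean, axis=0)
    if order == 1:
        return ll, grad
    hess = -(np.sum(s2 / s0[:, None, None], axis=0) - mean.T @ mean)
    return ll, grad, hess


def breslow_baseline(time: np.ndarray, event: np.ndarray, eta: np.ndarray):
    """Breslow estimate of the baseline cumulative hazard step function."""
    order = np.argsort(time, kind="stable")
    t, d, w = time[order], event[order], np.exp(eta[order])
    s0 = np.cumsum(w[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    ev = np.flatnonzero(d == 1)
    if ev.size == 0:
        return np.array([]), np.array([])
    tev = t[ev]
    uniq, counts = np.unique(tev, return_counts=True)
    # risk-set sum at each unique event time
    g = np.searchsorted(t, uniq, side="left")
    increments = counts / s0[g]
    return uniq, np.cumsum(increments)


@dataclass
class CoxFit:
    """Result of the Newton ascent: coefficients and convergence diagnostics."""

    coefficients: pd.Series
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n_iter: int
    converged: bool
    final_grad_norm: float
    loglik: float
    loglik_null: float


def fit_coxph(
    train: SurvivalDataset,
    terms: list[str] | None = None,
    include_interactions: bool = False,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Maximise the Breslow log partial likelihood by damped Newton ascent.

    Constant design columns are dropped before the fit (their coefficient is
    reported as 0).  Step-halving guarantees the log partial likelihood never
    decreases between iterations; non-convergence is flagged, not hidden.
    """
    check_has_events(train)
    design = expand_design(train.features, include_interactions=include_interactions)
    if terms is not None:
        design = design[list(terms)]
    keep = [c for c in design.columns if design[c].to_numpy().std() > 0]
    X = design[keep].to_numpy(dtype=float)
    time, event = train.time, train.event.astype(np.int8)

    beta = np.zeros(X.shape[1])
    ll_null = breslow_loglik(beta, X, time, event, order=0)
    ll = ll_null
    converged = False
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        ll, grad, hess = breslow_loglik(beta, X, time, event)
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < tol * max(1.0, abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving: never accept a non-finite or decreased partial
        # likelihood (guards against separation-driven divergence)
        scale = 1.0
        accepted = False
        for _ in range(30):
            ll_new = breslow_loglik(beta + scale * step, X, time, event, order=0)
            if np.isfinite(ll_new) and ll_new >= ll:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break  # no admissible ascent direction left; flag below
        beta = beta + scale * step
        ll = ll_new
    if not converged:
        warnings.warn(
            f"Cox Newton ascent did not converge in {max_iter} iterations "
            f"(|grad| = {grad_norm:.2e})",
            RuntimeWarning,
        )
    coefs = pd.Series(0.0, index=design.columns)
    coefs[keep] = beta
    eta = X @ beta
    bt, bh = breslow_baseline(time, event, eta)
    return CoxFit(coefs, bt, bh, it, converged, grad_norm, ll, ll_null)


class CoxPHModel(SurvivalPredictor):
    """Cox PH predictor under the common fit/predict contract.

    ``include_interactions`` appends the sex-by-COGSTAT dummy features to
    the design, the hand-coded way of letting the (otherwise homogeneous)
    linear model carry sex-specific cognitive-status effects.
    """

    name = "coxph"

    def __init__(self, include_interactions: bool = False, terms: list[str] | None = None):
        super().__init__()
        self.include_interactions = include_interactions
        self.terms = terms
        self.fit_: CoxFit | None = None

    def fit(self, train: SurvivalDataset) -> "CoxPHModel":
        self.fit_ = fit_coxph(
            train, terms=self.terms, include_interactions=self.include_interactions
        )
        self._fitted = True
        return self

    def _eta(self, features: pd.DataFrame) -> np.ndarray:
        design = expand_design(features, include_interactions=self.include_interactions)
        coefs = self.fit_.coefficients
        design = design[list(coefs.index)]
        return design.to_numpy(dtype=float) @ coefs.to_numpy()

    def predict_risk(self, features: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return self._eta(features)

    def predict_survival(self, features: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        """S(t | x) = exp(-Lambda0(t) * exp(eta))."""
        self._check_fitted()
        times = np.asarray(times, dtype=float)
        eta = self._eta(features)
        cumhaz = step_interpolate(
            self.fit_.baseline_times, self.fit_.baseline_cumhaz, times, left_value=0.0
        )
        return np.exp(-np.outer(np.exp(eta), cumhaz))
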