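"""Censoring-aware accuracy metrics.

Harrell's concordance index scores the ranking of risk predictions over
permissible pairs; the Brier score at a horizon t scores predicted survival
probabilities against observed status, reweighted for censoring by the
inverse-probability-of-censoring-weighting (IPCW) scheme

    BS(t) = (1/N) sum_i [ S_hat(t|x_i)^2 * 1{T_i <= t, delta_i = 1} / G_hat(T_i-)
                        + (1 - S_hat(t|x_i))^2 * 1{T_i > t} / G_hat(t) ]

where G_hat is a Kaplan-Meier estimate of the censoring survival function
(censoring treated as the event).  The integrated Brier score averages
BS(t) over [0, t_max] by trapezoidal quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

__all__ = [
    "MetricValue",
    "CensoringEstimate",
    "concordance_index",
    "fit_censoring_distribution",
    "brier_score",
    "brier_curve",
    "integrated_brier",
]


@dataclass(frozen=True)
class MetricValue:
    """A metric value together with how much evidence produced it."""

    metric: str
    value: float
    count: int  # evaluable pairs (C-index) or evaluated subjects/times


def concordance_index(
    times: np.ndarray,
    events: np.ndarray,
    scores: np.ndarray,
    tied_scores: str = "half",
) -> MetricValue:
    """Harrell's C over permissible pairs.

    A pair (i, j) is permissible when the shorter observed time belongs to a
    subject whose event was observed.  The pair is concordant when the
    earlier-failing subject carries the higher risk score.  ``tied_scores``
    = "half" credits tied scores 0.5 (the usual convention); "strict"
    credits them 0, i.e. the literal strict-inequality form.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not len(times) == len(events) == len(scores):
        raise ValueError("times, events and scores must have equal length")
    if tied_scores not in ("half", "strict"):
        raise ValueError("tied_scores must be 'half' or 'strict'")
    # pair (i, j) permissible iff T_i > T_j and subject j had the event
    longer = times[:, None] > times[None, :]
    permissible = longer & (events[None, :] == 1)
    n_pairs = int(permissible.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs: C-index is undefined")
    higher = scores[None, :] > scores[:, None]  # score_j > score_i
    concordant = int((permissible & higher).sum())
    value = concordant / n_pairs
    if tied_scores == "half":
        ties = int((permissible & (scores[None, :] == scores[:, None])).sum())
        value += 0.5 * ties / n_pairs
    return MetricValue("cindex", float(value), n_pairs)


@dataclass(frozen=True)
class CensoringEstimate:
    """Right-continuous step estimate G(t) of P(censoring time > t)."""

    times: np.ndarray  # sorted unique observed times
    surv: np.ndarray  # G at each time (right-continuous)

    def at(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)

    def at_left(self, t: np.ndarray) -> np.ndarray:
        """Left limit G(t-), the IPCW weight denominator for event terms."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="left") - 1
        return np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)


def fit_censoring_distribution(times: np.ndarray, events: np.ndarray) -> CensoringEstimate:
    """Kaplan-Meier product-limit estimate with censoring as the event."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if len(times) < 1:
        raise ValueError("at least one subject required")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=1 - events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)
    return CensoringEstimate(grid, vals)


def brier_score(
    t: float,
    times: np.ndarray,
    events: np.ndarray,
    survival_at_t: np.ndarray,
    censoring: CensoringEstimate,
) -> MetricValue:
    """IPCW Brier score at horizon ``t``.

    Subjects censored at or before ``t`` contribute nothing (their status at
    t is unknown; IPCW reassigns their mass to comparable subjects).  A
    subject whose required weight 1/G is undefined (G = 0) is excluded with
    a warning.  With no censoring present the estimator reduces exactly to
    the plain mean squared error between survival status and S_hat(t|x).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    s_hat = np.asarray(survival_at_t, dtype=float)
    if not len(times) == len(events) == len(s_hat):
        raise ValueError("length mismatch")
    n = len(times)
    had_event = (times <= t) & (events == 1)
    at_risk = times > t
    g_event = censoring.at_left(times)
    g_t = float(censoring.at(np.array([t]))[0])

    bad = (had_event & (g_event <= 0)) | (at_risk & (g_t <= 0))
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(
            f"excluding {n_bad} subjects with zero censoring-survival weight at t={t}",
            RuntimeWarning,
        )
    contrib = np.zeros(n)
    ok_event = had_event & ~bad
    contrib[ok_event] = (0.0 - s_hat[ok_event]) ** 2 / g_event[ok_event]
    ok_risk = at_risk & ~bad
    if np.any(ok_risk):
        contrib[ok_risk] = (1.0 - s_hat[ok_risk]) ** 2 / g_t
    value = float(contrib.sum() / (n - n_bad)) if n > n_bad else float("nan")
    return MetricValue("brier", value, n - n_bad)


def brier_curve(
    grid: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    survival_matrix: np.ndarray,
    censoring: CensoringEstimate,
) -> np.ndarray:
    """BS(t) for each t of ``grid``; survival_matrix is N x len(grid)."""
    grid = np.asarray(grid, dtype=float)
    return np.array(
        [
            brier_score(t, times, events, survival_matrix[:, k], censoring).value
            for k, t in enumerate(grid)
        ]
    )


def integrated_brier(grid: np.ndarray, bs_values: np.ndarray, t_max: float | None = None) -> MetricValue:
    """Trapezoidal average of BS(t) over [0, t_max]."""
    grid = np.asarray(grid, dtype=float)
    bs_values = np.asarray(bs_values, dtype=float)
    if t_max is None:
        t_max = float(grid[-1])
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if grid[0] != 0.0 or abs(grid[-1] - t_max) > 1e-12:
        raise ValueError("grid must start at 0 and end at t_max")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    value = float(np.trapezoid(bs_values, grid) / t_max)
    return MetricValue("ibs", value, len(grid))
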