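"""Cox-loss feed-forward neural network (DeepSurv-style).

A fully connected network maps the standardized design vector x to a scalar
log-risk h(x); hidden layers use ReLU followed by (inverted) dropout, the
output node is linear.  Training minimises the average negative log partial
likelihood of the training cohort

    L(theta) = -(1/D) sum_{events i} [ h(x_i) - log sum_{j in R(t_i)} e^{h(x_j)} ]
               + (lambda/2) * sum_l ||W_l||^2

(D = number of events, Breslow handling of ties) by full-batch Adam with
early stopping on a held-out slice of the training data.  Predicted
survival curves use the Breslow baseline hazard of the training cohort with
exp(h(x)) as the rate multiplier, exactly as for the linear Cox model.

The network is implemented directly on NumPy: the model is a few small
dense layers, and an explicit implementation keeps the loss, its gradient
and the update rule fully inspectable (the loss gradient reduces to
delta_j - e^{h_j} * Lambda0(T_j), the martingale residual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..datagen import SurvivalDataset, expand_design
from .base import SurvivalPredictor, check_has_events, step_interpolate
from .cox import breslow_baseline

__all__ = ["DeepSurvSpec", "DeepSurvModel", "neg_log_partial_likelihood"]


def neg_log_partial_likelihood(
    eta: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Average negative log partial likelihood of risk scores ``eta``."""
    d = int(np.sum(event))
    if d == 0:
        raise ValueError("no events in batch")
    order = np.argsort(time, kind="stable")
    t, dlt, e = time[order], np.asarray(event)[order], eta[order]
    shift = e.max()
    w = np.exp(e - shift)
    s0 = np.cumsum(w[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    ev = np.flatnonzero(dlt == 1)
    ll = np.sum(e[ev] - shift - np.log(s0[first[ev]]))
    return float(-ll / d)


def _loss_grad_eta(eta: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Loss and its gradient with respect to the risk scores.

    dL/deta_j = -(1/D) * (delta_j - e^{eta_j} * Lambda0(T_j)), with Lambda0
    the Breslow cumulative hazard of the current scores.
    """
    d = int(np.sum(event))
    loss = neg_log_partial_likelihood(eta, time, event)
    shift = eta.max()
    bt, bh = breslow_baseline(time, event, eta - shift)
    lam0 = step_interpolate(bt, bh, time, left_value=0.0)
    grad = -(event - np.exp(eta - shift) * lam0) / d
    return loss, grad


@dataclass(frozen=True)
class DeepSurvSpec:
    """Architecture and optimisation hyperparameters."""

    hidden_layers: tuple[int, ...] = (32, 32)
    dropout: float = 0.2
    activation: str = "relu"
    l2_penalty: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 500
    batch_size: int | None = None  # None = full batch
    patience: int = 20
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.activation != "relu":
            raise ValueError("only relu activations are supported")


class _MLP:
    """Minimal dense network: ReLU hidden layers, linear scalar head."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def forward(self, X, dropout=0.0, rng=None):
        """Returns (eta, cache) where cache holds activations and masks."""
        a = X
        acts, masks = [X], []
        for l, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if l < len(self.W) - 1:
                a = np.maximum(z, 0.0)
                if dropout > 0.0:
                    mask = (rng.uniform(size=a.shape) >= dropout) / (1.0 - dropout)
                    a = a * mask
                else:
                    mask = None
                masks.append(mask)
                acts.append(a)
            else:
                a = z
        return a[:, 0], (acts, masks)

    def backward(self, grad_eta, cache, l2):
        acts, masks = cache
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = grad_eta[:, None]
        for l in range(len(self.W) - 1, -1, -1):
            gW[l] = acts[l].T @ delta + l2 * self.W[l]
            gb[l] = delta.sum(axis=0)
            if l > 0:
                delta = delta @ self.W[l].T
                if masks[l - 1] is not None:
                    delta = delta * masks[l - 1]
                delta = delta * (acts[l] > 0)
        return gW, gb

    def params(self):
        return self.W + self.b

    def l2_term(self, l2):
        return 0.5 * l2 * sum(float(np.sum(W * W)) for W in self.W)


class DeepSurvModel(SurvivalPredictor):
    name = "deepsurv"

    def __init__(self, spec: DeepSurvSpec | None = None, random_state: int | None = None):
        super().__init__()
        self.spec = spec or DeepSurvSpec()
        self.random_state = random_state
        self.history_: list[tuple[float, float]] = []

    # -- internal helpers -------------------------------------------------

    def _design(self, features: pd.DataFrame) -> np.ndarray:
        design = expand_design(features)
        X = design[self._columns].to_numpy(dtype=float)
        return (X - self._mu) / self._sd

    def fit(self, train: SurvivalDataset) -> "DeepSurvModel":
        check_has_events(train)
        spec = self.spec
        rng = np.random.default_rng(self.random_state)
        design = expand_design(train.features)
        self._columns = list(design.columns)
        X = design.to_numpy(dtype=float)
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        X = (X - self._mu) / self._sd
        time, event = train.time, train.event.astype(float)

        # validation slice for early stopping (must contain events)
        n = len(X)
        n_val = int(round(spec.val_fraction * n))
        perm = rng.permutation(n)
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        if n_val < 2 or event[val_idx].sum() < 1 or event[fit_idx].sum() < 1:
            val_idx = np.array([], dtype=int)
            fit_idx = perm
        Xf, tf, ef = X[fit_idx], time[fit_idx], event[fit_idx]
        Xv, tv, ev = X[val_idx], time[val_idx], event[val_idx]

        sizes = [X.shape[1], *spec.hidden_layers, 1]
        net = _MLP(sizes, rng)
        params = net.params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0

        best_val = np.inf
        best_params = [p.copy() for p in params]
        since_best = 0
        self.history_ = []

        for epoch in range(spec.epochs):
            if spec.batch_size is None or spec.batch_size >= len(Xf):
                batches = [np.arange(len(Xf))]
            else:
                order = rng.permutation(len(Xf))
                batches = [
                    order[i : i + spec.batch_size]
                    for i in range(0, len(Xf), spec.batch_size)
                ]
            train_loss = np.nan
            for idx in batches:
                if ef[idx].sum() < 1:
                    continue
                eta, cache = net.forward(Xf[idx], dropout=spec.dropout, rng=rng)
                loss, grad_eta = _loss_grad_eta(eta, tf[idx], ef[idx])
                train_loss = loss + net.l2_term(spec.l2_penalty)
                if not np.isfinite(train_loss):
                    raise RuntimeError(
                        f"deepsurv training diverged at epoch {epoch}: "
                        f"loss={train_loss}, |eta|max={np.abs(eta).max():.3g}"
                    )
                gW, gb = net.backward(grad_eta, cache, spec.l2_penalty)
                grads = gW + gb
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi += (1 - b1) * (g - mi)
                    vi += (1 - b2) * (g * g - vi)
                    mhat = mi / (1 - b1**step)
                    vhat = vi / (1 - b2**step)
                    p -= spec.learning_rate * mhat / (np.sqrt(vhat) + eps)

            if len(val_idx) > 0:
                eta_v, _ = net.forward(Xv)
                monitor = neg_log_partial_likelihood(eta_v, tv, ev)
            else:
                eta_f, _ = net.forward(Xf)
                monitor = neg_log_partial_likelihood(eta_f, tf, ef)
            self.history_.append((float(train_loss), float(monitor)))
            if monitor < best_val - 1e-6:
                best_val = monitor
                best_params = [p.copy() for p in params]
                since_best = 0
            else:
                since_best += 1
                if since_best > spec.patience:
                    break

        for p, bp in zip(params, best_params):
            p[...] = bp
        self.net_ = net
        eta_all, _ = net.forward(X)
        self._eta_shift = float(np.mean(eta_all))
        bt, bh = breslow_baseline(time, train.event, eta_all - self._eta_shift)
        self._baseline = (bt, bh)
        self._fitted = True
        return self

    def predict_risk(self, features: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        eta, _ = self.net_.forward(self._design(features))
        return eta

    def predict_survival(self, features: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        self._check_fitted()
        times = np.asarray(times, dtype=float)
        eta = self.predict_risk(features) - self._eta_shift
        bt, bh = self._baseline
        cumhaz = step_interpolate(bt, bh, times, left_value=0.0)
        return np.exp(-np.outer(np.exp(eta), cumhaz))
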