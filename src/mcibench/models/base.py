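"""Common contract for the three benchmark survival predictors."""

from __future__ import annotations

import abc

import numpy as np
import pandas as pd

from ..datagen import SurvivalDataset


class NotFittedError(RuntimeError):
    pass


class SurvivalPredictor(abc.ABC):
    """Fit on a training cohort; emit risk scores and survival curves.

    Risk scores follow the hazard convention: a larger score means a higher
    hazard and hence an earlier expected event.  Predicted survival curves
    start at 1 at t = 0 and are non-increasing.
    """

    name: str = "model"

    def __init__(self) -> None:
        self._fitted = False

    @abc.abstractmethod
    def fit(self, train: SurvivalDataset) -> "SurvivalPredictor":
        ...

    @abc.abstractmethod
    def predict_risk(self, features: pd.DataFrame) -> np.ndarray:
        ...

    @abc.abstractmethod
    def predict_survival(self, features: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        """N x T matrix of S(t | x) over the given increasing time grid."""
        ...

    def _check_fitted(self) -> None:
        if not self._fitted:
            raise NotFittedError(f"{self.name} model is not fitted")


def check_has_events(train: SurvivalDataset) -> None:
    if int(np.sum(train.event)) < 1:
        raise ValueError("training data contain no observed events")


def step_interpolate(
    step_times: np.ndarray, step_values: np.ndarray, times: np.ndarray, left_value: float
) -> np.ndarray:
    """Right-continuous step-function lookup with a value before the first step."""
    idx = np.searchsorted(step_times, times, side="right") - 1
    out = np.where(idx >= 0, step_values[np.clip(idx, 0, None)], left_value)
    return out
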