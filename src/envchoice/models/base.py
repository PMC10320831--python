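"""Common estimator interface and registry for the choice-model zoo.

Every model follows the scikit-learn estimator contract: hyperparameters in
``__init__``, a ``fit(X, y)`` that learns parameters (suffixed ``_``), and
``predict_proba(X)`` returning ``(n, 2)`` choice probabilities with column
order (left, right). ``X`` is a tidy trial table in the
:mod:`envchoice.datasets` dialect, already filtered to the model's stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ..stats import softmax2

__all__ = ["ChoiceModel", "register_model", "make_model", "available_models"]

_REGISTRY: dict[str, tuple[type, dict]] = {}


class ModelRegistryError(KeyError):
    pass


def register_model(model_id: str, **fixed_kwargs):
    """Class decorator adding a model to the string-addressed registry.

    ``fixed_kwargs`` are constructor arguments baked into the id (used for
    the simplified-CNN variants, which share one class).
    """

    def deco(cls):
        if not fixed_kwargs:
            cls.model_id = model_id
        _REGISTRY[model_id] = (cls, fixed_kwargs)
        return cls

    return deco


def make_model(model_id: str, **kwargs) -> "ChoiceModel":
    try:
        cls, fixed = _REGISTRY[model_id]
    except KeyError:
        raise ModelRegistryError(
            f"unknown model id {model_id!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return cls(**{**fixed, **kwargs})


def available_models() -> list[str]:
    return sorted(_REGISTRY)


class ChoiceModel(BaseEstimator):
    """Base class: binary choice via softmax over two decision values."""

    model_id: str = "base"
    stage: int = 1  # which task stage the model scores

    # --- contract -------------------------------------------------------
    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        """(n, 2) decision values (left, right)."""
        raise NotImplementedError

    def fit(self, X: pd.DataFrame, y: np.ndarray | None = None) -> "ChoiceModel":
        raise NotImplementedError

    # --- shared behaviour ----------------------------------------------
    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return softmax2(self.decision_values(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """1 = right, 0 = left; ties (P = 0.5) go to left."""
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def nll(self, X: pd.DataFrame, y: np.ndarray | None = None) -> float:
        """Total negative log likelihood of the made choices."""
        y = self._resolve_choices(X, y)
        p = self.predict_proba(X)
        chosen = np.clip(p[np.arange(len(y)), y], 1e-12, None)
        return float(-np.sum(np.log(chosen)))

    def accuracy(self, X: pd.DataFrame, y: np.ndarray | None = None) -> float:
        """Fraction of trials where P(made choice) > 0.5 (ties count as wrong)."""
        y = self._resolve_choices(X, y)
        p = self.predict_proba(X)
        return float(np.mean(p[np.arange(len(y)), y] > 0.5))

    @staticmethod
    def _resolve_choices(X: pd.DataFrame, y: np.ndarray | None) -> np.ndarray:
        if y is None:
            if "choice" not in X:
                raise ValueError("no choices supplied and X lacks a 'choice' column")
            y = X["choice"].to_numpy()
        y = np.asarray(y, dtype=int)
        if y.shape[0] != len(X):
            raise ValueError("y length does not match X")
        return y
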