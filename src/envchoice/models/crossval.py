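"""20-fold cross-validated fitting and NLL-based model comparison.

Choices are pooled across subjects, randomly split into ``folds`` subsets,
and each model is trained on all-but-one subset and scored on the held-out
one. Goodness of fit is the held-out negative log likelihood, recorded both
as a per-fold sum and as a per-trial mean; models are compared by
independent-samples t-tests on the per-trial fold NLLs (df = 38 for two
20-fold models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from ..datasets import ChoiceDataset
from .base import make_model

__all__ = ["ModelFit", "make_folds", "fit_model", "compare_models"]


def make_folds(n_trials: int, folds: int, seed: int) -> np.ndarray:
    """Random fold label (0..folds-1) per trial; disjoint, exhaustive, seeded."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n_trials < folds:
        raise ValueError("fewer trials than folds")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_trials) % folds
    return labels[rng.permutation(n_trials)]


@dataclass
class ModelFit:
    """Cross-validated fit record for one model on one dataset."""

    model_id: str
    fold_nll: np.ndarray            # held-out NLL sum per fold
    fold_nll_per_trial: np.ndarray  # held-out NLL per trial, averaged per fold
    fold_assignment: np.ndarray
    trial_prob: np.ndarray          # held-out P(made choice) per trial
    accuracy: float                 # fraction of held-out trials with P(choice) > 0.5
    seed: int
    fold_params: list = field(default_factory=list)
    fold_models: list = field(default_factory=list, repr=False)

    @property
    def mean_nll(self) -> float:
        return float(np.mean(self.fold_nll_per_trial))

    @property
    def sem_nll(self) -> float:
        return float(sps.sem(self.fold_nll_per_trial))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_id": self.model_id,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "fold_nll": self.fold_nll.tolist(),
            "fold_nll_per_trial": self.fold_nll_per_trial.tolist(),
            "fold_assignment": self.fold_assignment.tolist(),
            "trial_prob": self.trial_prob.tolist(),
            "fold_params": self.fold_params,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _params_of(model) -> dict | None:
    """JSON-serializable snapshot of a fitted model's learned parameters."""
    if hasattr(model, "params_"):
        return {k: float(v) for k, v in model.params_.items()}
    out = {}
    for name in ("W1_", "b1_", "W2_", "b2_", "W3_", "b3_"):
        if hasattr(model, name):
            out[name] = np.asarray(getattr(model, name)).tolist()
    return out or None


def fit_model(model_id: str, dataset: ChoiceDataset, folds: int = 20,
              seed: int = 0, stage: int | None = None,
              keep_models: bool = False, **model_kwargs) -> ModelFit:
    """Cross-validated fit of a registered model to a pooled choice dataset."""
    probe = make_model(model_id, **model_kwargs)
    stage = stage if stage is not None else probe.stage
    if "stage" in probe.get_params():
        model_kwargs.setdefault("stage", stage)
    df = dataset.stage(stage)
    if df.empty:
        raise ValueError(f"dataset has no stage-{stage} trials")
    y = df["choice"].to_numpy(dtype=int)
    n = len(df)
    assignment = make_folds(n, folds, seed)

    fold_nll = np.zeros(folds)
    fold_nll_pt = np.zeros(folds)
    trial_prob = np.full(n, np.nan)
    hits = 0
    fold_params: list = []
    fold_models: list = []
    for k in range(folds):
        test = assignment == k
        train = ~test
        model = make_model(model_id, **model_kwargs)
        if "seed" in model.get_params():
            model.set_params(seed=seed * 1000 + k)
        model.fit(df[train].reset_index(drop=True), y[train])
        p = model.predict_proba(df[test].reset_index(drop=True))
        p_chosen = np.clip(p[np.arange(test.sum()), y[test]], 1e-12, None)
        trial_prob[test] = p_chosen
        fold_nll[k] = float(-np.log(p_chosen).sum())
        fold_nll_pt[k] = fold_nll[k] / test.sum()
        hits += int(np.sum(p_chosen > 0.5))
        fold_params.append(_params_of(model))
        if keep_models:
            fold_models.append(model)
    return ModelFit(model_id=model_id, fold_nll=fold_nll,
                    fold_nll_per_trial=fold_nll_pt, fold_assignment=assignment,
                    trial_prob=trial_prob, accuracy=hits / n, seed=seed,
                    fold_params=fold_params, fold_models=fold_models)


def compare_models(fits: list[ModelFit]) -> dict[str, pd.DataFrame]:
    """Mean +/- SEM table and pairwise independent-samples t-tests on fold NLLs."""
    if not fits:
        raise ValueError("no fits supplied")
    table = pd.DataFrame({
        "model": [f.model_id for f in fits],
        "mean_nll": [f.mean_nll for f in fits],
        "sem_nll": [f.sem_nll for f in fits],
        "accuracy": [f.accuracy for f in fits],
    }).sort_values("mean_nll").reset_index(drop=True)

    rows = []
    for i, a in enumerate(fits):
        for j, b in enumerate(fits):
            if j <= i:
                continue
            xa, xb = a.fold_nll_per_trial, b.fold_nll_per_trial
            if np.allclose(xa, xb):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(xa, xb)
            rows.append({"model_a": a.model_id, "model_b": b.model_id,
                         "t": float(t), "p": float(p),
                         "df": len(xa) + len(xb) - 2})
    return {"table": table, "pairwise": pd.DataFrame(rows)}
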