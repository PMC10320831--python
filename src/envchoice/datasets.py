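"""Tidy per-trial choice data containers and CSV round-tripping.

A :class:`ChoiceDataset` holds one row per trial for any number of simulated
agents (or loaded participants). Stage-1 rows carry the full 20-item
probability vectors of both environments (columns ``pL00..pL19`` /
``pR00..pR19``) together with the displayed mean magnitudes; stage-2 rows
carry the two drawn items' scalar probabilities and magnitudes in the same
``prob_left/prob_right`` / ``mag_left/mag_right`` columns.

Column dictionary
-----------------
subject            integer agent/participant id
block              block index within subject
stage              1 (environment choice) or 2 (item choice)
trial_in_block     0 for the stage-1 trial, 1..3 for item trials
onset              stimulus onset time in seconds within the subject's run
bonus              block bonus value
bonus_condition    1 = linked, 0 = unlinked
prob_left/right    mean env probability (stage 1) or item probability (stage 2)
mag_left/right     displayed mean magnitude (stage 1) or item magnitude (stage 2)
valence_left/right gain or loss
pL00..pL19,        per-item environment reward probabilities
pR00..pR19         (stage-1 rows only; NaN on stage-2 rows)
choice             1 = right chosen, 0 = left chosen
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task import N_ITEMS

__all__ = ["ChoiceDataset", "PROB_COLS_LEFT", "PROB_COLS_RIGHT"]

PROB_COLS_LEFT = [f"pL{i:02d}" for i in range(N_ITEMS)]
PROB_COLS_RIGHT = [f"pR{i:02d}" for i in range(N_ITEMS)]

_SCALAR_COLS = [
    "subject", "block", "stage", "trial_in_block", "onset",
    "bonus", "bonus_condition", "prob_left", "prob_right",
    "mag_left", "mag_right", "valence_left", "valence_right", "choice",
]


@dataclass
class ChoiceDataset:
    """Per-trial choice records plus generation metadata."""

    trials: pd.DataFrame
    agent_params: dict | None = None
    n_subjects: int = 1
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _SCALAR_COLS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trials table missing columns: {missing}")

    def stage(self, which: int) -> pd.DataFrame:
        return self.trials[self.trials["stage"] == which].reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def subjects(self) -> list[int]:
        return sorted(self.trials["subject"].unique().tolist())

    def to_csv(self, path: str | Path) -> None:
        """Write the trial table as CSV with a JSON sidecar for metadata."""
        path = Path(path)
        self.trials.to_csv(path, index=False)
        sidecar = {
            "agent_params": self.agent_params,
            "n_subjects": self.n_subjects,
            "config": self.config,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChoiceDataset":
        """Load a trial table; accepts externally supplied tables in the same dialect."""
        path = Path(path)
        trials = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        n_subjects = meta.get("n_subjects", trials["subject"].nunique())
        return cls(trials=trials, agent_params=meta.get("agent_params"),
                   n_subjects=n_subjects, config=meta.get("config", {}),
                   seed=meta.get("seed"))


def stage1_arrays(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Dense arrays for stage-1 model evaluation.

    Returns probs (n, 20, 2), mag (n, 2), bonus (n,), cond (n,), and, when
    present, choice (n,) with 1 = right.
    """
    pl = df[PROB_COLS_LEFT].to_numpy(dtype=float)
    pr = df[PROB_COLS_RIGHT].to_numpy(dtype=float)
    out = {
        "probs": np.stack([pl, pr], axis=2),
        "mag": df[["mag_left", "mag_right"]].to_numpy(dtype=float),
        "bonus": df["bonus"].to_numpy(dtype=float),
        "cond": df["bonus_condition"].to_numpy(dtype=float),
    }
    if "choice" in df and not df["choice"].isna().all():
        out["choice"] = df["choice"].to_numpy(dtype=int)
    return out


def stage2_arrays(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Dense arrays for stage-2 (item choice) model evaluation."""
    out = {
        "probs": df[["prob_left", "prob_right"]].to_numpy(dtype=float),
        "mag": df[["mag_left", "mag_right"]].to_numpy(dtype=float),
        "bonus": df["bonus"].to_numpy(dtype=float),
        "cond": df["bonus_condition"].to_numpy(dtype=float),
    }
    if "choice" in df and not df["choice"].isna().all():
        out["choice"] = df["choice"].to_numpy(dtype=int)
    return out
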