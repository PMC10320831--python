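"""Choice-generating agents with known parameters.

An agent is any registered decision model plus a softmax temperature. Given
a task design, the agent's analytic choice probabilities are computed per
trial and choices are sampled; stage-2 item pairs are resolved from the
environment the agent actually chose at stage 1, honoring the block
linkage. The generating parameters are recorded on the returned dataset so
recovery analyses can compare against ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import PROB_COLS_LEFT, PROB_COLS_RIGHT, ChoiceDataset
from .models.base import make_model
from .stats import softmax2
from .task import TaskConfig, TaskDesign, generate_task

__all__ = ["simulate_agent", "simulate_cohort"]


def _sample_from_dv(dv: np.ndarray, temperature: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample right/left choices from temperature-scaled softmax of DVs."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if temperature == 0:
        diff = dv[:, 1] - dv[:, 0]
        p_right = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    else:
        p_right = softmax2(dv / temperature)[:, 1]
    return (rng.random(len(p_right)) < p_right).astype(int), p_right


def _stage1_frame(task: TaskDesign, subject: int) -> pd.DataFrame:
    cfg = task.config
    rows = []
    t = 0.0
    for b_idx, blk in enumerate(task.blocks):
        row = {
            "subject": subject, "block": b_idx, "stage": 1, "trial_in_block": 0,
            "onset": t, "bonus": blk.bonus, "bonus_condition": blk.bonus_condition,
            "prob_left": blk.env_left.mean_prob, "prob_right": blk.env_right.mean_prob,
            "mag_left": blk.env_left.mean_mag, "mag_right": blk.env_right.mean_mag,
            "valence_left": blk.env_left.valence, "valence_right": blk.env_right.valence,
        }
        row.update(dict(zip(PROB_COLS_LEFT, blk.env_left.item_probs)))
        row.update(dict(zip(PROB_COLS_RIGHT, blk.env_right.item_probs)))
        rows.append(row)
        t += cfg.stage1_duration + blk.n_item_trials * cfg.stage2_duration + cfg.iti
    return pd.DataFrame(rows)


def _stage2_frame(task: TaskDesign, stage1_choices: np.ndarray,
                  subject: int) -> pd.DataFrame:
    cfg = task.config
    rows = []
    t = 0.0
    for b_idx, blk in enumerate(task.blocks):
        env = blk.env_right if stage1_choices[b_idx] == 1 else blk.env_left
        t_item = t + cfg.stage1_duration
        for k, (i, j) in enumerate(blk.item_pairs):
            rows.append({
                "subject": subject, "block": b_idx, "stage": 2,
                "trial_in_block": k + 1, "onset": t_item,
                "bonus": blk.bonus, "bonus_condition": blk.bonus_condition,
                "prob_left": env.item_probs[i], "prob_right": env.item_probs[j],
                "mag_left": env.item_mags[i], "mag_right": env.item_mags[j],
                "valence_left": env.valence, "valence_right": env.valence,
            })
            t_item += cfg.stage2_duration
        t += cfg.stage1_duration + blk.n_item_trials * cfg.stage2_duration + cfg.iti
    df = pd.DataFrame(rows)
    if not df.empty:
        for c in PROB_COLS_LEFT + PROB_COLS_RIGHT:
            df[c] = np.nan
    return df


def simulate_agent(task: TaskDesign, model_id: str, params: dict | None = None,
                   temperature: float = 1.0, seed: int = 0, n_subjects: int = 1,
                   stage2_model_id: str | None = None,
                   stage2_params: dict | None = None,
                   **model_kwargs) -> ChoiceDataset:
    """Simulate choices from a named decision model on a task design.

    The same design is replayed for every subject with independent choice
    noise; use :func:`simulate_cohort` for per-subject designs. Stage-2
    choices come from ``stage2_model_id`` (default: the stage-1 model if it
    scores items, otherwise an EV chooser).
    """
    rng = np.random.default_rng(seed)
    model1 = _build_agent_model(model_id, params, stage=1, **model_kwargs)
    if stage2_model_id is None:
        stage2_model_id = model_id if _supports_stage2(model_id) else "ev"
        stage2_params = stage2_params if stage2_params is not None else (
            params if _supports_stage2(model_id) else {"beta": 1.0})
    model2 = _build_agent_model(stage2_model_id, stage2_params, stage=2)

    frames = []
    for s in range(n_subjects):
        df1 = _stage1_frame(task, subject=s)
        dv1 = model1.decision_values(df1)
        c1, p1 = _sample_from_dv(dv1, temperature, rng)
        df1["choice"] = c1
        df1["p_right_model"] = p1
        df2 = _stage2_frame(task, c1, subject=s)
        if not df2.empty:
            dv2 = model2.decision_values(df2)
            c2, p2 = _sample_from_dv(dv2, temperature, rng)
            df2["choice"] = c2
            df2["p_right_model"] = p2
        frames.append(pd.concat([df1, df2], ignore_index=True))
    trials = pd.concat(frames, ignore_index=True)
    trials = trials.sort_values(["subject", "block", "trial_in_block"]).reset_index(drop=True)
    agent_params = {"model": model_id, "params": params, "temperature": temperature,
                    "stage2_model": stage2_model_id, "stage2_params": stage2_params}
    return ChoiceDataset(trials=trials, agent_params=agent_params,
                         n_subjects=n_subjects, config=task.config.to_dict(),
                         seed=seed)


def simulate_cohort(agent: dict, n_subjects: int, seed: int = 0,
                    task_config: TaskConfig | None = None) -> ChoiceDataset:
    """Fresh task design per subject, then agent simulation, concatenated."""
    rng = np.random.default_rng(seed)
    datasets = []
    for s in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        task = generate_task(task_config, seed=sub_seed)
        ds = simulate_agent(task, seed=sub_seed + 1, n_subjects=1, **agent)
        ds.trials["subject"] = s
        datasets.append(ds)
    trials = pd.concat([d.trials for d in datasets], ignore_index=True)
    cfg = (task_config or TaskConfig()).to_dict()
    return ChoiceDataset(trials=trials, agent_params=datasets[0].agent_params,
                         n_subjects=n_subjects, config=cfg, seed=seed)


def _supports_stage2(model_id: str) -> bool:
    return model_id in ("glm", "ev", "cpt", "autoencoder", "ann")


def _build_agent_model(model_id: str, params, stage: int, **kwargs):
    if model_id in ("cnn", "ann") and isinstance(params, dict) and "W2" in params:
        return make_model(model_id, weights=params, **kwargs)
    model = make_model(model_id, **kwargs)
    own = model.get_params()
    if "stage" in own:
        model.set_params(stage=stage)
    if params is not None:
        if hasattr(model, "param_start"):
            model.params = params
        else:
            raise ValueError(f"model {model_id!r} needs explicit weights to act as an agent")
    elif not hasattr(model, "params_") and not hasattr(model, "W2_"):
        raise ValueError(f"agent model {model_id!r} has no parameters")
    return model
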