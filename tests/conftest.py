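import numpy as np
import pandas as pd
import pytest

import envchoice as ec
from envchoice.datasets import PROB_COLS_LEFT, PROB_COLS_RIGHT


def make_stage1_frame(probs_l, probs_r, mag_l, mag_r, bonus=0.0, cond=0,
                      choice=None):
    """Build a stage-1 trial table from explicit environment arrays.

    probs_l/probs_r: (n, 20); mag/bonus/cond scalars or (n,) arrays.
    """
    probs_l = np.atleast_2d(np.asarray(probs_l, float))
    probs_r = np.atleast_2d(np.asarray(probs_r, float))
    n = probs_l.shape[0]

    def vec(x):
        return np.broadcast_to(np.asarray(x, float), (n,)).copy()

    mag_l, mag_r, bonus, cond = vec(mag_l), vec(mag_r), vec(bonus), vec(cond)
    df = pd.DataFrame({
        "subject": 0, "block": np.arange(n), "stage": 1, "trial_in_block": 0,
        "onset": np.arange(n) * 10.0, "bonus": bonus, "bonus_condition": cond,
        "prob_left": probs_l.mean(axis=1), "prob_right": probs_r.mean(axis=1),
        "mag_left": mag_l, "mag_right": mag_r,
        "valence_left": np.where(mag_l >= 0, "gain", "loss"),
        "valence_right": np.where(mag_r >= 0, "gain", "loss"),
    })
    df[PROB_COLS_LEFT] = probs_l
    df[PROB_COLS_RIGHT] = probs_r
    if choice is not None:
        df["choice"] = np.broadcast_to(np.asarray(choice, int), (n,)).copy()
    return df


@pytest.fixture(scope="session")
def small_task():
    cfg = ec.TaskConfig(n_stage1=40, n_stage2=40)
    return ec.generate_task(cfg, seed=7)


@pytest.fixture(scope="session")
def mvs_dataset(small_task):
    """Choices of a variance-seeking agent on the small task, 4 subjects."""
    return ec.simulate_agent(
        small_task, "mvs",
        {"rho": 1.0, "sigma": 0.0, "b1": 0.3, "b2": 3.0, "b5": 0.15, "b6": 0.2},
        temperature=1.0, seed=3, n_subjects=4)


@pytest.fixture(scope="session")
def trained_cnn(mvs_dataset):
    cnn = ec.make_model("cnn", n_hidden=16, n_epochs=150, seed=0)
    return cnn.fit(mvs_dataset.stage(1))
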