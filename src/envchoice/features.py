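"""Feature-detector decomposition of a fitted CNN's decision value.

The CNN's DV is a weighted combination of all feature maps. Keeping one
detector's feature maps and zeroing the rest (post-convolution, network
weights untouched) yields that detector's "partial DV"; correlating the
per-trial partial-DV differences with the trial's differences in
environment mean, variance, and skewness shows which statistical moments
each detector extracts. Dependent correlations sharing one variable are
compared with Steiger's z.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import PROB_COLS_LEFT, PROB_COLS_RIGHT
from .models.networks import CnnChoiceModel
from .stats import moments, steiger_z

__all__ = ["partial_dv", "partial_dv_table", "moment_correlations",
           "compare_dependent_correlations"]

MOMENT_COLS = ["mean_diff", "var_diff", "skew_diff"]


def partial_dv(model: CnnChoiceModel, X: pd.DataFrame, detector: int) -> np.ndarray:
    """Per-trial DV difference (right - left) using only one detector's maps."""
    dv = model.partial_decision_values(X, detector)
    return dv[:, 1] - dv[:, 0]


def partial_dv_table(model: CnnChoiceModel, X: pd.DataFrame) -> pd.DataFrame:
    """One row per stage-1 trial: per-detector partial DV differences plus
    the moment differences between the two environments."""
    ml = moments(X[PROB_COLS_LEFT].to_numpy(float))
    mr = moments(X[PROB_COLS_RIGHT].to_numpy(float))
    out = {f"partial_dv_{d}": partial_dv(model, X, d)
           for d in range(model.n_detectors)}
    out["mean_diff"] = mr["mean"] - ml["mean"]
    out["var_diff"] = mr["variance"] - ml["variance"]
    out["skew_diff"] = mr["skewness"] - ml["skewness"]
    return pd.DataFrame(out)


def moment_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (with two-tailed p) of each detector's partial DV against
    each moment difference."""
    detectors = [c for c in table.columns if c.startswith("partial_dv_")]
    rows = []
    for det in detectors:
        for mom in MOMENT_COLS:
            r, p = sps.pearsonr(table[det], table[mom])
            rows.append({"detector": int(det.rsplit("_", 1)[1]), "moment": mom,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def compare_dependent_correlations(r1: float, r2: float, r12: float,
                                   n: int) -> tuple[float, float]:
    """Steiger's z for H0: r(x, y1) = r(x, y2) with r(y1, y2) = r12."""
    return steiger_z(r1, r2, r12, n)
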