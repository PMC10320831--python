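"""Behavioral logistic regressions on choice data.

Two designs are supported, each fitted per subject by maximum likelihood
and summarized by group one-sample t-tests (df = n_subjects - 1):

* GLM1 — logit P(right) on EV difference, probability difference, bonus,
  bonus condition, and the two three-way bonus-adaptation interactions
  (EV x Bon x Cond, Prob x Bon x Cond). Applicable to either stage.
* GLM2 — logit P(right) on EV difference plus the differences in mean,
  variance, and skewness of the two environments' item-probability
  distributions (stage 1 only).

Regressors are z-scored within subject by default (the binary condition
dummy keeps its 1/0 coding); population (/n) moments are used. Subjects
whose fit separates perfectly or fails to converge are flagged and excluded
from the group test with a warning rather than contributing infinite
coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import PROB_COLS_LEFT, PROB_COLS_RIGHT, ChoiceDataset
from .stats import moments

__all__ = ["GlmResult", "BehavioralGlm", "fit_glm1", "fit_glm2", "moments"]

GLM1_TERMS = ["intercept", "ev_diff", "prob_diff", "bonus", "cond",
              "ev_bon_cond", "prob_bon_cond"]
GLM2_TERMS = ["intercept", "ev_diff", "mean_diff", "var_diff", "skew_diff"]


@dataclass
class GlmResult:
    """Per-subject coefficients and group-level one-sample t statistics."""

    coefficients: pd.DataFrame       # index subject, columns terms
    group: pd.DataFrame              # term, mean, t, df, p
    flagged_subjects: list[int] = field(default_factory=list)


def _glm1_design(df: pd.DataFrame) -> pd.DataFrame:
    ev_l = df["mag_left"] * df["prob_left"]
    ev_r = df["mag_right"] * df["prob_right"]
    ev_d = ev_r - ev_l
    prob_d = df["prob_right"] - df["prob_left"]
    bon = df["bonus"]
    cond = df["bonus_condition"]
    return pd.DataFrame({
        "ev_diff": ev_d, "prob_diff": prob_d, "bonus": bon, "cond": cond,
        "ev_bon_cond": ev_d * bon * cond, "prob_bon_cond": prob_d * bon * cond,
    })


def _glm2_design(df: pd.DataFrame) -> pd.DataFrame:
    probs_l = df[PROB_COLS_LEFT].to_numpy(float)
    probs_r = df[PROB_COLS_RIGHT].to_numpy(float)
    ml, mr = moments(probs_l), moments(probs_r)
    ev_l = df["mag_left"] * df["prob_left"]
    ev_r = df["mag_right"] * df["prob_right"]
    return pd.DataFrame({
        "ev_diff": (ev_r - ev_l).to_numpy(),
        "mean_diff": mr["mean"] - ml["mean"],
        "var_diff": mr["variance"] - ml["variance"],
        "skew_diff": mr["skewness"] - ml["skewness"],
    })


class BehavioralGlm:
    """Per-subject logistic regression with group one-sample inference.

    Parameters
    ----------
    design : {"glm1", "glm2"}
    stage : 1 or 2 (glm2 implies stage 1)
    zscore : standardize continuous regressors within subject
    coef_limit : |coefficient| beyond which a subject is flagged as separated
    """

    def __init__(self, design: str = "glm1", stage: int = 1,
                 zscore: bool = True, coef_limit: float = 50.0):
        if design not in ("glm1", "glm2"):
            raise ValueError("design must be 'glm1' or 'glm2'")
        self.design = design
        self.stage = 1 if design == "glm2" else stage
        self.zscore = zscore
        self.coef_limit = coef_limit

    @property
    def terms(self) -> list[str]:
        return GLM1_TERMS if self.design == "glm1" else GLM2_TERMS

    def _subject_design(self, df: pd.DataFrame) -> np.ndarray:
        X = _glm1_design(df) if self.design == "glm1" else _glm2_design(df)
        X = X.to_numpy(float)
        if self.zscore:
            names = self.terms[1:]
            for j, name in enumerate(names):
                if name == "cond":  # keep the 1/0 dummy coding
                    continue
                sd = X[:, j].std()
                if sd > 0:
                    X[:, j] = (X[:, j] - X[:, j].mean()) / sd
        return np.column_stack([np.ones(len(X)), X])

    def _fit_subject(self, df: pd.DataFrame) -> tuple[np.ndarray | None, str]:
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        y = df["choice"].to_numpy(int)
        if len(np.unique(y)) < 2:
            return None, "single-class choices"
        X = self._subject_design(df)
        if np.any(np.ptp(X[:, 1:], axis=0) == 0):
            return None, "degenerate regressor (no variance)"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as e:
            return None, f"fit failed: {type(e).__name__}"
        coef = np.asarray(res.params)
        if not res.mle_retvals.get("converged", True):
            return None, "no convergence"
        if np.any(np.abs(coef) > self.coef_limit) or not np.all(np.isfinite(coef)):
            return None, "separation (unbounded coefficient)"
        return coef, ""

    def fit(self, dataset: ChoiceDataset) -> GlmResult:
        df = dataset.stage(self.stage)
        if df.empty:
            raise ValueError(f"no stage-{self.stage} trials")
        subjects = sorted(df["subject"].unique())
        rows, flagged = {}, []
        for s in subjects:
            coef, why = self._fit_subject(df[df["subject"] == s])
            if coef is None:
                flagged.append(int(s))
                warnings.warn(f"subject {s} excluded from {self.design}: {why}",
                              RuntimeWarning)
            else:
                rows[s] = coef
        if len(rows) < 2:
            raise ValueError("fewer than 2 usable subjects for group inference")
        coefs = pd.DataFrame.from_dict(rows, orient="index", columns=self.terms)
        group_rows = []
        for term in self.terms:
            vals = coefs[term].to_numpy()
            t, p = sps.ttest_1samp(vals, 0.0)
            group_rows.append({"term": term, "mean": float(vals.mean()),
                               "t": float(t), "df": len(vals) - 1, "p": float(p)})
        return GlmResult(coefficients=coefs, group=pd.DataFrame(group_rows),
                         flagged_subjects=flagged)


def fit_glm1(dataset: ChoiceDataset, stage: int = 1, **kwargs) -> GlmResult:
    return BehavioralGlm(design="glm1", stage=stage, **kwargs).fit(dataset)


def fit_glm2(dataset: ChoiceDataset, **kwargs) -> GlmResult:
    return BehavioralGlm(design="glm2", **kwargs).fit(dataset)
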