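"""Parametric decision-value models: GLM-DV, EV, MVS, power-law, and CPT.

All stage-1 models reduce an environment's 20 item probabilities to a
subjective probability ``prob_hat`` and combine it with the displayed mean
magnitude, the block bonus, and the bonus condition into a decision value

    DV_k = b1*Mag_k + b2*prob_hat_k + b3*Bon + b4*Cond
           + b5*(Mag_k * prob_hat_k) + b6*(prob_hat_k * Bon * Cond)

whose softmax over the two options gives the choice probability. (CPT
additionally transforms the magnitude into ``mag_hat``.) The GLM-DV model
instead scores a single rightward DV through a logistic link; both variants
expose the same ``predict_proba`` contract.

Fitting is bounded maximum likelihood with multi-start L-BFGS-B.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ..datasets import stage1_arrays, stage2_arrays
from ..stats import moments
from .base import ChoiceModel, register_model

__all__ = [
    "GlmDvModel", "ExpectedValueModel", "MvsModel", "PowerLawModel",
    "CptModel", "mvs_subjective_prob", "power_subjective_prob",
    "cpt_weight", "cpt_value", "assemble_dv",
]


# ---------------------------------------------------------------------------
# subjective-value primitives

def mvs_subjective_prob(probs: np.ndarray, rho: float, sigma: float) -> np.ndarray:
    """Mean-variance-skewness subjective probability of an item bundle."""
    m = moments(probs)
    return m["mean"] + rho * m["variance"] + sigma * m["skewness"]


def power_subjective_prob(probs: np.ndarray, g: float) -> np.ndarray:
    """Mean of item probabilities each transduced by a power g > 0."""
    if g <= 0:
        raise ValueError("power g must be positive")
    return np.mean(np.asarray(probs, float) ** g, axis=-1)


def cpt_weight(p: np.ndarray, gamma: float) -> np.ndarray:
    """Inverse-S probability weighting w(p) = p^g / (p^g + (1-p)^g)^(1/g)."""
    p = np.asarray(p, dtype=float)
    num = p ** gamma
    den = (num + (1.0 - p) ** gamma) ** (1.0 / gamma)
    return num / den


def cpt_value(mag: np.ndarray, alpha: float, beta: float, lam: float) -> np.ndarray:
    """Power value function with loss aversion lambda."""
    mag = np.asarray(mag, dtype=float)
    return np.where(mag >= 0, np.abs(mag) ** alpha, -lam * np.abs(mag) ** beta)


def assemble_dv(mag_hat: np.ndarray, prob_hat: np.ndarray, bonus: np.ndarray,
                cond: np.ndarray, b: dict[str, float]) -> np.ndarray:
    """The shared six-term DV combination; mag/prob arrays are (n, 2)."""
    bon = bonus[:, None]
    cnd = cond[:, None]
    return (b["b1"] * mag_hat + b["b2"] * prob_hat + b["b3"] * bon + b["b4"] * cnd
            + b["b5"] * mag_hat * prob_hat + b["b6"] * prob_hat * bon * cnd)


_BETA_NAMES = ["b1", "b2", "b3", "b4", "b5", "b6"]
_BETA_BOUNDS = {n: (-20.0, 20.0) for n in _BETA_NAMES}
_BETA_START = {"b1": 0.1, "b2": 0.5, "b3": 0.0, "b4": 0.0, "b5": 0.1, "b6": 0.0}


class ParametricChoiceModel(ChoiceModel):
    """Shared bounded-MLE machinery. Subclasses define the DV."""

    param_names: list[str] = []
    param_bounds: dict[str, tuple[float, float]] = {}
    param_start: dict[str, float] = {}
    #: parameters actually optimized; the rest stay at their start values.
    #: For per-side DV models the b3 (bonus) and b4 (condition) terms shift
    #: both options' DVs equally, cancel in the softmax, and are therefore
    #: not identifiable from choices -- they are held fixed during fitting.
    free_param_names: list[str] | None = None

    def __init__(self, params: dict | None = None, stage: int = 1,
                 n_restarts: int = 10, max_iter: int = 500, seed: int = 0):
        self.params = params
        self.stage = stage
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.seed = seed

    # -- data access ----------------------------------------------------
    def _arrays(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        if self.stage == 1:
            return stage1_arrays(X)
        arrs = stage2_arrays(X)
        arrs = dict(arrs)
        arrs["probs"] = arrs["probs"][:, None, :]  # (n, 1 item, 2)
        return arrs

    # -- parameters ------------------------------------------------------
    def _theta(self) -> dict[str, float]:
        if hasattr(self, "params_"):
            return self.params_
        if self.params is not None:
            theta = dict(self.param_start)
            theta.update(self.params)
            return theta
        raise ValueError(f"{type(self).__name__} has neither fixed params nor a fit")

    def _dv(self, theta: dict[str, float], arrs: dict[str, np.ndarray]) -> np.ndarray:
        raise NotImplementedError

    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        return self._dv(self._theta(), self._arrays(X))

    # -- fitting ---------------------------------------------------------
    def fit(self, X: pd.DataFrame, y: np.ndarray | None = None) -> "ParametricChoiceModel":
        y = self._resolve_choices(X, y)
        arrs = self._arrays(X)
        names = self.free_param_names or self.param_names
        fixed = {n: self.param_start[n] for n in self.param_names if n not in names}
        bounds = [self.param_bounds[n] for n in names]
        idx = np.arange(len(y))

        def objective(vec: np.ndarray) -> float:
            theta = {**fixed, **dict(zip(names, vec))}
            dv = self._dv(theta, arrs)
            dv = dv - dv.max(axis=1, keepdims=True)
            logp = dv - np.log(np.exp(dv).sum(axis=1))[:, None]
            return float(-logp[idx, y].sum())

        rng = np.random.default_rng(self.seed)
        best = None
        n_converged = 0
        for r in range(self.n_restarts):
            if r == 0:
                x0 = np.array([self.param_start[n] for n in names])
            else:
                x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
            res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": self.max_iter})
            n_converged += bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if n_converged == 0:
            import warnings
            warnings.warn(f"{type(self).__name__}: no restart reported convergence; "
                          "best candidate retained", RuntimeWarning)
        self.params_ = {**fixed, **dict(zip(names, best.x))}
        self.nll_ = float(best.fun)
        self.converged_ = n_converged > 0
        return self


@register_model("glm")
class GlmDvModel(ParametricChoiceModel):
    """Logistic DV model on (R-L) differences; the EV-based regression baseline."""

    param_names = ["b0"] + _BETA_NAMES
    param_bounds = {"b0": (-20.0, 20.0), **_BETA_BOUNDS}
    param_start = {"b0": 0.0, **_BETA_START}

    def _dv(self, t, arrs):
        mag = arrs["mag"]
        prob = arrs["probs"].mean(axis=1)  # (n, 2) mean probabilities
        dv_r = (t["b0"] + t["b1"] * (mag[:, 1] - mag[:, 0])
                + t["b2"] * (prob[:, 1] - prob[:, 0])
                + t["b3"] * arrs["bonus"] + t["b4"] * arrs["cond"]
                + t["b5"] * (mag[:, 1] * prob[:, 1] - mag[:, 0] * prob[:, 0])
                + t["b6"] * (prob[:, 1] - prob[:, 0]) * arrs["bonus"] * arrs["cond"])
        return np.column_stack([np.zeros_like(dv_r), dv_r])


@register_model("ev")
class ExpectedValueModel(ParametricChoiceModel):
    """Single-parameter softmax over expected values (mean mag x mean prob)."""

    param_names = ["beta"]
    param_bounds = {"beta": (0.0, 50.0)}
    param_start = {"beta": 1.0}

    def _dv(self, t, arrs):
        ev = arrs["mag"] * arrs["probs"].mean(axis=1)
        return t["beta"] * ev


class _SubjectiveProbModel(ParametricChoiceModel):
    """Base for models that only reshape the probability bundle."""

    @property
    def free_param_names(self):
        return [n for n in self.param_names if n not in ("b3", "b4")]

    def _prob_hat(self, t, arrs):
        raise NotImplementedError

    def _dv(self, t, arrs):
        prob_hat = self._prob_hat(t, arrs)
        return assemble_dv(arrs["mag"], prob_hat, arrs["bonus"], arrs["cond"], t)


@register_model("mvs")
class MvsModel(_SubjectiveProbModel):
    """Mean-variance-skewness preferences over the item-probability bundle."""

    param_names = ["rho", "sigma"] + _BETA_NAMES
    param_bounds = {"rho": (-5.0, 5.0), "sigma": (-5.0, 5.0), **_BETA_BOUNDS}
    param_start = {"rho": 0.0, "sigma": 0.0, **_BETA_START}

    def _prob_hat(self, t, arrs):
        # environment moments are parameter-free; cache them on the arrays
        # dict so repeated objective evaluations during fitting reuse them
        if "_moments" not in arrs:
            arrs["_moments"] = moments(arrs["probs"].transpose(0, 2, 1))
        m = arrs["_moments"]
        return m["mean"] + t["rho"] * m["variance"] + t["sigma"] * m["skewness"]


@register_model("power")
class PowerLawModel(_SubjectiveProbModel):
    """Item probabilities transduced by a power g before averaging."""

    param_names = ["g"] + _BETA_NAMES
    param_bounds = {"g": (0.05, 5.0), **_BETA_BOUNDS}
    param_start = {"g": 1.0, **_BETA_START}

    def _prob_hat(self, t, arrs):
        return power_subjective_prob(arrs["probs"].transpose(0, 2, 1), t["g"])


@register_model("cpt")
class CptModel(ParametricChoiceModel):
    """Cumulative prospect theory with valence-specific probability weighting.

    Gains use the gamma weighting function, losses the delta one; the
    magnitude passes through a power value function with loss aversion
    lambda. The gamma/delta bounds keep the weighting function numerically
    monotone-safe.
    """

    param_names = ["alpha", "beta", "lam", "gamma", "delta"] + _BETA_NAMES
    param_bounds = {"alpha": (0.2, 1.5), "beta": (0.2, 1.5), "lam": (0.0, 5.0),
                    "gamma": (0.2, 1.5), "delta": (0.2, 1.5), **_BETA_BOUNDS}
    param_start = {"alpha": 1.0, "beta": 1.0, "lam": 1.0, "gamma": 1.0,
                   "delta": 1.0, **_BETA_START}

    @property
    def free_param_names(self):
        return [n for n in self.param_names if n not in ("b3", "b4")]

    def _dv(self, t, arrs):
        mag = arrs["mag"]                         # (n, 2)
        probs = arrs["probs"].transpose(0, 2, 1)  # (n, 2, items)
        mag_hat = cpt_value(mag, t["alpha"], t["beta"], t["lam"])
        w_gain = cpt_weight(probs, t["gamma"]).mean(axis=-1)
        w_loss = cpt_weight(probs, t["delta"]).mean(axis=-1)
        prob_hat = np.where(mag >= 0, w_gain, w_loss)
        return assemble_dv(mag_hat, prob_hat, arrs["bonus"], arrs["cond"], t)
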