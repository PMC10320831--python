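"""Network choice models: stage-1 CNN, simplified CNNs, stage-2 ANN, autoencoder.

The stage-1 CNN receives the 20 x 2 matrix of item reward probabilities
(items x environments). A bank of F feature detectors of size M x N
(default four 2 x 1 detectors) slides along the items with stride 1 and no
padding, producing F feature maps of size 19 x 2. The concatenated feature
vector is

    concat = [feature maps; mean magnitudes; feature maps x magnitude;
              bonus; condition]

(order fixed by this module), which a fully connected ReLU layer maps to
``n_hidden`` nodes and a final linear layer maps to two decision values;
softmax over the DVs gives the choice probability. Simplified variants
replace the 20-item input by explicit moment summaries (mean/variance/
skewness per environment) and skip the convolution; the stage-2 ANN feeds
the two items' values directly into concat; the autoencoder uses a sigmoid
hidden layer on hand-listed value features.

All networks are small numpy models trained full-batch on the softmax
cross-entropy with hand-written gradients (Adam by default, plain gradient
descent available), with early stopping on a training-loss plateau. Every
input channel is z-scored with constants estimated on the training data and
stored on the fitted model for re-use at test time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datasets import stage1_arrays, stage2_arrays
from ..stats import moments, softmax2
from .base import ChoiceModel, register_model

__all__ = [
    "convolve", "CnnChoiceModel", "SimplifiedCnnChoiceModel",
    "AnnChoiceModel", "AutoencoderChoiceModel",
]


def convolve(X: np.ndarray, W: np.ndarray, b: float = 0.0) -> np.ndarray:
    """Valid cross-correlation of a detector over an input matrix.

    Output entry (i, j) = b + sum_mn W[m, n] * X[i+m, j+n]; no flipping,
    stride 1, no padding. The detector must fit inside X.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    I, J = X.shape
    M, N = W.shape
    if M > I or N > J:
        raise ValueError(f"detector {W.shape} larger than input {X.shape}")
    out = np.full((I - M + 1, J - N + 1), float(b))
    for m in range(M):
        for n in range(N):
            out += W[m, n] * X[m:m + I - M + 1, n:n + J - N + 1]
    return out


class _Adam:
    """Minimal Adam stepper over a list of arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _GradientDescent:
    def __init__(self, params, lr):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


class _NetworkModel(ChoiceModel):
    """Shared feature -> ReLU/sigmoid hidden -> 2-DV machinery."""

    hidden_activation = "relu"

    def _features(self, X: pd.DataFrame) -> np.ndarray:
        """(n, d) standardized concat features; subclass-specific."""
        raise NotImplementedError

    def _feature_dim(self) -> int:
        raise NotImplementedError

    # -- forward ---------------------------------------------------------
    def _hidden(self, F: np.ndarray) -> np.ndarray:
        pre = F @ self.W2_.T + self.b2_
        if self.hidden_activation == "relu":
            return np.maximum(pre, 0.0)
        return 1.0 / (1.0 + np.exp(-pre))

    def _dv_from_features(self, F: np.ndarray) -> np.ndarray:
        return self._hidden(F) @ self.W3_.T + self.b3_

    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        return self._dv_from_features(self._features(X))

    def layer_activations(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        """Per-trial activations of every layer (for RSA)."""
        F = self._features(X)
        Y = self._hidden(F)
        dv = Y @ self.W3_.T + self.b3_
        if not np.all(np.isfinite(dv)):
            raise FloatingPointError("non-finite activation in final_fc layer")
        return {"input": F, "hidden": Y, "final_fc": dv}

    # -- training --------------------------------------------------------
    def _init_mlp(self, rng: np.random.Generator, d: int) -> None:
        h = self.n_hidden
        s = np.sqrt(2.0 / d)
        self.W2_ = rng.normal(0.0, s, size=(h, d))
        self.b2_ = np.zeros(h)
        self.W3_ = rng.normal(0.0, np.sqrt(2.0 / h), size=(2, h))
        self.b3_ = np.zeros(2)

    def _conv_params(self) -> list[np.ndarray]:
        return []

    def _conv_backward(self, dF: np.ndarray, cache) -> list[np.ndarray]:
        return []

    def _train(self, build, y: np.ndarray) -> None:
        """build() -> (features, cache); cache feeds the conv backward pass."""
        n = len(y)
        onehot = np.zeros((n, 2))
        onehot[np.arange(n), y] = 1.0
        params = self._conv_params() + [self.W2_, self.b2_, self.W3_, self.b3_]
        opt = (_Adam(params, self.learning_rate) if self.optimizer == "adam"
               else _GradientDescent(params, self.learning_rate))
        history: list[float] = []
        best = np.inf
        stale = 0
        for _ in range(self.n_epochs):
            F, cache = build()
            pre = F @ self.W2_.T + self.b2_
            if self.hidden_activation == "relu":
                Y = np.maximum(pre, 0.0)
            else:
                Y = 1.0 / (1.0 + np.exp(-pre))
            dv = Y @ self.W3_.T + self.b3_
            P = softmax2(dv)
            nll = float(-np.sum(np.log(np.clip(P[np.arange(n), y], 1e-12, None))))
            history.append(nll / n)

            dDV = (P - onehot) / n
            gW3 = dDV.T @ Y
            gb3 = dDV.sum(axis=0)
            dY = dDV @ self.W3_
            if self.hidden_activation == "relu":
                dpre = dY * (pre > 0)
            else:
                dpre = dY * Y * (1.0 - Y)
            wd = getattr(self, "weight_decay", 0.0)
            gW2 = dpre.T @ F + wd * self.W2_
            gb2 = dpre.sum(axis=0)
            gW3 += wd * self.W3_
            dF = dpre @ self.W2_
            conv_grads = self._conv_backward(dF, cache)
            opt.step(params, conv_grads + [gW2, gb2, gW3, gb3])

            if nll < best - self.tol * n:
                best, stale = nll, 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        self.loss_history_ = np.asarray(history)

    def fit(self, X: pd.DataFrame, y: np.ndarray | None = None):
        y = self._resolve_choices(X, y)
        rng = np.random.default_rng(self.seed)
        self._fit_norms(X)
        self._init_net(rng)
        self._train(lambda: self._build_training_features(X), y)
        return self

    # subclasses implement _fit_norms, _init_net, _build_training_features


def _zscore(x: np.ndarray, stats: tuple[float, float]) -> np.ndarray:
    mu, sd = stats
    return (x - mu) / sd


def _norm_stats(x: np.ndarray) -> tuple[float, float]:
    sd = float(np.std(x))
    return float(np.mean(x)), (sd if sd > 0 else 1.0)


@register_model("cnn")
class CnnChoiceModel(_NetworkModel):
    """The stage-1 environment-choice CNN (see module docstring)."""

    stage = 1

    def __init__(self, n_detectors: int = 4, detector_shape: tuple[int, int] = (2, 1),
                 n_hidden: int = 512, learning_rate: float = 0.01,
                 n_epochs: int = 600, tol: float = 1e-6, patience: int = 30,
                 optimizer: str = "adam", weight_decay: float = 1e-2,
                 standardize: bool = True,
                 seed: int = 0, weights: dict | None = None):
        self.n_detectors = n_detectors
        self.weight_decay = weight_decay
        self.detector_shape = tuple(detector_shape)
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.tol = tol
        self.patience = patience
        self.optimizer = optimizer
        self.standardize = standardize
        self.seed = seed
        self.weights = weights
        if weights is not None:
            self._set_weights(weights)

    @classmethod
    def moment_preference_weights(cls, n_items: int = 20,
                                  dispersion_weight: float = 1.0,
                                  ev_weight: float = 0.04,
                                  big_bias: float = 500.0) -> dict:
        """Hand-constructed CNN agent with nonlinear moment preferences.

        Detector 0 is a difference kernel [1, -1]; paired ReLU units rectify
        each map entry so the readout sums |p_(i+1) - p_i| per environment —
        a total-variation dispersion preference no linear-in-EV model can
        express. Detector 1 is a local-mean kernel whose magnitude-weighted
        map provides an expected-value channel (kept linear by a large bias
        that the readout bias cancels).
        """
        Io, Jo = n_items - 1, 2
        W1 = np.array([[[1.0], [-1.0]], [[0.5], [0.5]]])
        b1 = np.zeros(2)
        fm_sz = 2 * Io * Jo
        D = 2 * fm_sz + 2 + 2

        def idx(f, i, j, mag=False):
            return (fm_sz + 2 if mag else 0) + f * Io * Jo + i * Jo + j

        H = 2 * Io * Jo + 2
        W2 = np.zeros((H, D))
        b2 = np.zeros(H)
        W3 = np.zeros((2, H))
        h = 0
        for i in range(Io):
            for j in range(Jo):
                for sign in (1.0, -1.0):
                    W2[h, idx(0, i, j)] = sign
                    W3[j, h] = dispersion_weight
                    h += 1
        for j in range(Jo):
            for i in range(Io):
                W2[h, idx(1, i, j, mag=True)] = 1.0
            b2[h] = big_bias
            W3[j, h] = ev_weight
            h += 1
        b3 = np.full(2, -ev_weight * big_bias)
        return {"W1": W1, "b1": b1, "W2": W2, "b2": b2, "W3": W3, "b3": b3}

    @classmethod
    def random_weights(cls, n_detectors: int = 4, detector_shape=(2, 1),
                       n_hidden: int = 16, n_items: int = 20, seed: int = 0,
                       scale: float = 1.0) -> dict:
        """Random weight set for constructing a CNN agent with known ground truth."""
        rng = np.random.default_rng(seed)
        M, N = detector_shape
        Io, Jo = n_items - M + 1, 2 - N + 1
        d = 2 * n_detectors * Io * Jo + 2 + 2
        return {
            "W1": rng.normal(0, 1.0, size=(n_detectors, M, N)),
            "b1": rng.normal(0, 0.2, size=n_detectors),
            "W2": rng.normal(0, scale * np.sqrt(2.0 / d), size=(n_hidden, d)),
            "b2": np.zeros(n_hidden),
            "W3": rng.normal(0, scale * np.sqrt(2.0 / n_hidden), size=(2, n_hidden)),
            "b3": np.zeros(2),
        }

    def _set_weights(self, w: dict) -> None:
        self.W1_ = np.asarray(w["W1"], float)
        self.n_detectors = self.W1_.shape[0]
        self.detector_shape = self.W1_.shape[1:]
        self.b1_ = np.asarray(w["b1"], float)
        self.W2_ = np.asarray(w["W2"], float)
        self.b2_ = np.asarray(w["b2"], float)
        self.W3_ = np.asarray(w["W3"], float)
        self.b3_ = np.asarray(w["b3"], float)
        self.norms_ = w.get("norms", {"prob": (0.0, 1.0), "mag": (0.0, 1.0),
                                      "bonus": (0.0, 1.0)})

    # -- input assembly --------------------------------------------------
    def _inputs(self, X: pd.DataFrame):
        arrs = stage1_arrays(X)
        probs = arrs["probs"]                    # (n, I, J)
        mag = arrs["mag"]                        # (n, J)
        if probs.shape[1] < self.detector_shape[0] or probs.shape[2] < self.detector_shape[1]:
            raise ValueError("detector larger than the item-probability input")
        norms = getattr(self, "norms_", None)
        if self.standardize and norms is not None:
            probs = _zscore(probs, norms["prob"])
            mag = _zscore(mag, norms["mag"])
            bonus = _zscore(arrs["bonus"], norms["bonus"])
        else:
            bonus = arrs["bonus"]
        return probs, mag, bonus, arrs["cond"]

    def build_input(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        """Network input per trial: the items x environments probability
        matrix (column order left, right), the magnitude vector, and the
        bonus/condition scalars, standardized per the fitted constants."""
        probs, mag, bonus, cond = self._inputs(X)
        return {"prob_matrix": probs, "magnitude": mag,
                "bonus": bonus, "condition": cond}

    def _feature_maps_from(self, probs: np.ndarray) -> np.ndarray:
        """(n, F, Io, Jo) batched valid cross-correlation."""
        n, I, J = probs.shape
        M, N = self.detector_shape
        Io, Jo = I - M + 1, J - N + 1
        fm = np.tile(self.b1_[None, :, None, None], (n, 1, Io, Jo)).astype(float)
        for m in range(M):
            for nn in range(N):
                fm += (self.W1_[:, m, nn][None, :, None, None]
                       * probs[:, m:m + Io, nn:nn + Jo][:, None, :, :])
        return fm

    def feature_maps(self, X: pd.DataFrame) -> np.ndarray:
        probs, _, _, _ = self._inputs(X)
        return self._feature_maps_from(probs)

    def _mag_factor(self, mag: np.ndarray, Jo: int) -> np.ndarray:
        # each environment's magnitude scales its column of every feature map;
        # if the map lost the environment axis, fall back to the mean magnitude
        if Jo == mag.shape[1]:
            return mag[:, None, None, :]
        return mag.mean(axis=1)[:, None, None, None]

    def _concat(self, fm: np.ndarray, mag: np.ndarray, bonus: np.ndarray,
                cond: np.ndarray, keep: np.ndarray | None = None) -> np.ndarray:
        n = fm.shape[0]
        fmm = fm * self._mag_factor(mag, fm.shape[3])
        if keep is not None:
            fm = fm * keep[None, :, None, None]
            fmm = fmm * keep[None, :, None, None]
        return np.concatenate([fm.reshape(n, -1), mag, fmm.reshape(n, -1),
                               bonus[:, None], cond[:, None]], axis=1)

    def _features(self, X: pd.DataFrame, keep: np.ndarray | None = None) -> np.ndarray:
        probs, mag, bonus, cond = self._inputs(X)
        fm = self._feature_maps_from(probs)
        return self._concat(fm, mag, bonus, cond, keep=keep)

    def partial_decision_values(self, X: pd.DataFrame, detector: int) -> np.ndarray:
        """DVs with all feature maps except ``detector``'s zeroed post-convolution."""
        if not 0 <= detector < self.n_detectors:
            raise IndexError(f"detector {detector} out of range 0..{self.n_detectors - 1}")
        keep = np.zeros(self.n_detectors)
        keep[detector] = 1.0
        return self._dv_from_features(self._features(X, keep=keep))

    def baseline_decision_values(self, X: pd.DataFrame) -> np.ndarray:
        """DVs with every feature map zeroed (bias/bonus-only forward pass)."""
        return self._dv_from_features(self._features(X, keep=np.zeros(self.n_detectors)))

    # -- training hooks --------------------------------------------------
    def _fit_norms(self, X: pd.DataFrame) -> None:
        arrs = stage1_arrays(X)
        if self.standardize:
            self.norms_ = {"prob": _norm_stats(arrs["probs"]),
                           "mag": _norm_stats(arrs["mag"]),
                           "bonus": _norm_stats(arrs["bonus"])}
        else:
            self.norms_ = {"prob": (0.0, 1.0), "mag": (0.0, 1.0), "bonus": (0.0, 1.0)}

    def _init_net(self, rng: np.random.Generator) -> None:
        M, N = self.detector_shape
        F = self.n_detectors
        self.W1_ = rng.normal(0.0, 0.5, size=(F, M, N))
        self.b1_ = np.zeros(F)
        # feature dimension: 2 * F * Io * Jo + J + 2
        I, J = 20, 2
        Io, Jo = I - M + 1, J - N + 1
        self._fm_shape = (F, Io, Jo)
        self._init_mlp(rng, 2 * F * Io * Jo + J + 2)

    def _conv_params(self):
        return [self.W1_, self.b1_]

    def _build_training_features(self, X: pd.DataFrame):
        probs, mag, bonus, cond = self._inputs(X)
        fm = self._feature_maps_from(probs)
        F_ = self._concat(fm, mag, bonus, cond)
        return F_, (probs, mag, fm.shape)

    def _conv_backward(self, dF: np.ndarray, cache):
        probs, mag, fm_shape = cache
        n, I, J = probs.shape
        Fd, Io, Jo = fm_shape[1], fm_shape[2], fm_shape[3]
        sz = Fd * Io * Jo
        dfm_direct = dF[:, :sz].reshape(n, Fd, Io, Jo)
        dfm_mag = dF[:, sz + J: 2 * sz + J].reshape(n, Fd, Io, Jo)
        dfm = dfm_direct + dfm_mag * self._mag_factor(mag, Jo)
        M, N = self.detector_shape
        gW1 = np.zeros_like(self.W1_)
        for m in range(M):
            for nn in range(N):
                gW1[:, m, nn] = np.einsum("nfij,nij->f", dfm,
                                          probs[:, m:m + Io, nn:nn + Jo])
        gb1 = dfm.sum(axis=(0, 2, 3))
        return [gW1, gb1]


_VARIANT_MOMENTS = {
    "mean": ["mean"],
    "mean+var": ["mean", "variance"],
    "mean+skew": ["mean", "skewness"],
    "var+skew": ["variance", "skewness"],
    "mean+var+skew": ["mean", "variance", "skewness"],
}


class SimplifiedCnnChoiceModel(_NetworkModel):
    """Moment-summary variant: the 20-item input is replaced by explicit
    statistical moments per environment and the convolution is skipped."""

    stage = 1

    def __init__(self, variant: str = "mean+var+skew", n_hidden: int = 512,
                 learning_rate: float = 0.01, n_epochs: int = 600,
                 tol: float = 1e-6, patience: int = 30, optimizer: str = "adam",
                 weight_decay: float = 1e-2, standardize: bool = True,
                 seed: int = 0):
        self.weight_decay = weight_decay
        if variant not in _VARIANT_MOMENTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.tol = tol
        self.patience = patience
        self.optimizer = optimizer
        self.standardize = standardize
        self.seed = seed

    def moment_inputs(self, X: pd.DataFrame) -> np.ndarray:
        """(n, c, 2) raw moment summaries per environment."""
        arrs = stage1_arrays(X)
        m = moments(arrs["probs"].transpose(0, 2, 1))  # values (n, 2)
        return np.stack([m[k] for k in _VARIANT_MOMENTS[self.variant]], axis=1)

    def _raw(self, X: pd.DataFrame):
        arrs = stage1_arrays(X)
        return self.moment_inputs(X), arrs["mag"], arrs["bonus"], arrs["cond"]

    def _features(self, X: pd.DataFrame) -> np.ndarray:
        s, mag, bonus, cond = self._raw(X)
        norms = getattr(self, "norms_", None)
        if self.standardize and norms is not None:
            s = (s - norms["s_mean"][None, :, None]) / norms["s_std"][None, :, None]
            mag = _zscore(mag, norms["mag"])
            bonus = _zscore(bonus, norms["bonus"])
        n = len(mag)
        smag = s * mag[:, None, :]
        return np.concatenate([s.reshape(n, -1), mag, smag.reshape(n, -1),
                               bonus[:, None], cond[:, None]], axis=1)

    def _fit_norms(self, X: pd.DataFrame) -> None:
        s, mag, bonus, _ = self._raw(X)
        if self.standardize:
            sd = s.std(axis=(0, 2))
            self.norms_ = {"s_mean": s.mean(axis=(0, 2)),
                           "s_std": np.where(sd > 0, sd, 1.0),
                           "mag": _norm_stats(mag), "bonus": _norm_stats(bonus)}
        else:
            c = s.shape[1]
            self.norms_ = {"s_mean": np.zeros(c), "s_std": np.ones(c),
                           "mag": (0.0, 1.0), "bonus": (0.0, 1.0)}

    def _init_net(self, rng: np.random.Generator) -> None:
        c = len(_VARIANT_MOMENTS[self.variant])
        self._init_mlp(rng, 2 * c + 2 + 2 * c + 2)

    def _build_training_features(self, X: pd.DataFrame):
        return self._features(X), None


SimplifiedCnnChoiceModel.model_id = "simplified_cnn"
for _v, _id in [("mean", "cnn_mean"), ("mean+var", "cnn_mean_var"),
                ("mean+skew", "cnn_mean_skew"), ("var+skew", "cnn_var_skew"),
                ("mean+var+skew", "cnn_mean_var_skew")]:
    register_model(_id, variant=_v)(SimplifiedCnnChoiceModel)


@register_model("ann")
class AnnChoiceModel(_NetworkModel):
    """Stage-2 item-choice network: the CNN without the convolution stage."""

    stage = 2

    def __init__(self, n_hidden: int = 512, learning_rate: float = 0.01,
                 n_epochs: int = 600, tol: float = 1e-6, patience: int = 30,
                 optimizer: str = "adam", weight_decay: float = 1e-2,
                 standardize: bool = True,
                 seed: int = 0, weights: dict | None = None):
        self.n_hidden = n_hidden
        self.weight_decay = weight_decay
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.tol = tol
        self.patience = patience
        self.optimizer = optimizer
        self.standardize = standardize
        self.seed = seed
        self.weights = weights
        if weights is not None:
            self.W2_ = np.asarray(weights["W2"], float)
            self.b2_ = np.asarray(weights["b2"], float)
            self.W3_ = np.asarray(weights["W3"], float)
            self.b3_ = np.asarray(weights["b3"], float)
            self.norms_ = weights.get("norms", {"prob": (0.0, 1.0), "mag": (0.0, 1.0),
                                                "bonus": (0.0, 1.0)})

    def _raw(self, X: pd.DataFrame):
        arrs = stage2_arrays(X)
        return arrs["probs"], arrs["mag"], arrs["bonus"], arrs["cond"]

    def _features(self, X: pd.DataFrame) -> np.ndarray:
        probs, mag, bonus, cond = self._raw(X)
        norms = getattr(self, "norms_", None)
        if self.standardize and norms is not None:
            probs = _zscore(probs, norms["prob"])
            mag = _zscore(mag, norms["mag"])
            bonus = _zscore(bonus, norms["bonus"])
        return np.concatenate([probs, mag, probs * mag,
                               bonus[:, None], cond[:, None]], axis=1)

    def _fit_norms(self, X: pd.DataFrame) -> None:
        probs, mag, bonus, _ = self._raw(X)
        if self.standardize:
            self.norms_ = {"prob": _norm_stats(probs), "mag": _norm_stats(mag),
                           "bonus": _norm_stats(bonus)}
        else:
            self.norms_ = {"prob": (0.0, 1.0), "mag": (0.0, 1.0), "bonus": (0.0, 1.0)}

    def _init_net(self, rng: np.random.Generator) -> None:
        self._init_mlp(rng, 8)

    def _build_training_features(self, X: pd.DataFrame):
        return self._features(X), None


@register_model("autoencoder")
class AutoencoderChoiceModel(_NetworkModel):
    """Sigmoid-hidden network on hand-listed value features.

    Input per option pair: Mag, Prob, Bon, Cond, Mag x Prob, and
    Prob x Bon x Cond, listed for both options where option-specific.
    """

    hidden_activation = "sigmoid"

    def __init__(self, n_hidden: int = 512, stage: int = 1,
                 learning_rate: float = 0.01, n_epochs: int = 600,
                 tol: float = 1e-6, patience: int = 30, optimizer: str = "adam",
                 weight_decay: float = 1e-2, standardize: bool = True,
                 seed: int = 0):
        self.n_hidden = n_hidden
        self.weight_decay = weight_decay
        self.stage = stage
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.tol = tol
        self.patience = patience
        self.optimizer = optimizer
        self.standardize = standardize
        self.seed = seed

    def _raw(self, X: pd.DataFrame):
        if self.stage == 1:
            arrs = stage1_arrays(X)
            probs = arrs["probs"].mean(axis=1)
        else:
            arrs = stage2_arrays(X)
            probs = arrs["probs"]
        return probs, arrs["mag"], arrs["bonus"], arrs["cond"]

    def _features(self, X: pd.DataFrame) -> np.ndarray:
        probs, mag, bonus, cond = self._raw(X)
        norms = getattr(self, "norms_", None)
        if self.standardize and norms is not None:
            probs = _zscore(probs, norms["prob"])
            mag = _zscore(mag, norms["mag"])
            bonus = _zscore(bonus, norms["bonus"])
        bc = (bonus * cond)[:, None]
        return np.concatenate([mag, probs, bonus[:, None], cond[:, None],
                               mag * probs, probs * bc], axis=1)

    def _fit_norms(self, X: pd.DataFrame) -> None:
        probs, mag, bonus, _ = self._raw(X)
        if self.standardize:
            self.norms_ = {"prob": _norm_stats(probs), "mag": _norm_stats(mag),
                           "bonus": _norm_stats(bonus)}
        else:
            self.norms_ = {"prob": (0.0, 1.0), "mag": (0.0, 1.0), "bonus": (0.0, 1.0)}

    def _init_net(self, rng: np.random.Generator) -> None:
        self._init_mlp(rng, 10)

    def _build_training_features(self, X: pd.DataFrame):
        return self._features(X), None
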