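"""Low-level statistical helpers shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["moments", "softmax2", "steiger_z"]


def moments(probs: np.ndarray) -> dict[str, np.ndarray]:
    """Population mean, variance, and standardized skewness of item probabilities.

    Works on a single environment ``(n_items,)`` or a batch
    ``(..., n_items)``; moments are taken over the last axis. Zero-variance
    input yields skewness 0 by convention.
    """
    p = np.asarray(probs, dtype=float)
    mean = p.mean(axis=-1)
    centered = p - mean[..., None]
    var = np.mean(centered ** 2, axis=-1)
    m3 = np.mean(centered ** 3, axis=-1)
    # variance indistinguishable from rounding noise counts as degenerate
    tiny = 1e-20 * np.maximum(1.0, mean ** 2)
    var = np.where(var > tiny, var, 0.0)
    denom = np.where(var > 0, var, 1.0) ** 1.5
    skew = np.where(var > 0, m3 / denom, 0.0)
    if np.ndim(probs) == 1:
        return {"mean": float(mean), "variance": float(var), "skewness": float(skew)}
    return {"mean": mean, "variance": var, "skewness": skew}


def softmax2(dv: np.ndarray) -> np.ndarray:
    """Row-wise softmax over the last axis, shift-invariant and overflow-safe."""
    dv = np.asarray(dv, dtype=float)
    z = dv - dv.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def steiger_z(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's test for two dependent correlations sharing one variable.

    Compares r(x, y1) = ``r1`` with r(x, y2) = ``r2`` given r(y1, y2) =
    ``r12`` over ``n`` observations. Returns (z, two-tailed p).
    """
    from scipy import stats as sps

    for r in (r1, r2, r12):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rm2 = (r1 ** 2 + r2 ** 2) / 2.0
    f = min((1.0 - r12) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
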