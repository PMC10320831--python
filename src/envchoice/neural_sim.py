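"""Synthetic multivariate patterns and BOLD-like time series.

Two generators cover the downstream analyses:

* trial x unit activation *patterns* with planted representational
  structure — a random affine mixing of source activations (for example a
  model layer) plus Gaussian noise, one independent mixing per simulated
  subject, so RSA pipelines can be validated against known ground truth;
* TR-sampled *time series* — an HRF-convolved event design times planted
  amplitudes plus AR(1) noise, so time-course regression and PPI recover
  known effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timecourse import TR_DEFAULT, DesignSpec

__all__ = ["SyntheticNeural", "simulate_patterns", "simulate_bold", "simulate_neural"]


@dataclass
class SyntheticNeural:
    """Synthetic region data plus the generator that planted its structure."""

    patterns: dict[int, np.ndarray] = field(default_factory=dict)
    timeseries: dict[int, np.ndarray] = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)


def simulate_patterns(source: np.ndarray, n_units: int = 50, noise_sd: float = 1.0,
                      n_subjects: int = 1, seed: int = 0) -> SyntheticNeural:
    """Affine random mixing of source activations per trial plus Gaussian noise.

    ``source`` is a (n_trials, k) activation matrix (e.g. a model layer);
    each subject receives an independent mixing matrix and noise draw.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    src = np.asarray(source, float)
    rng = np.random.default_rng(seed)
    k = src.shape[1]
    if n_units < k + 1:
        raise ValueError("n_units must exceed the source dimensionality")
    # row-center the source so pairwise Pearson geometry is well defined
    src = src - src.mean(axis=1, keepdims=True)
    patterns = {}
    for s in range(n_subjects):
        # mixing with orthonormal, zero-mean columns: preserves the source's
        # correlation RDM exactly at noise_sd = 0
        G = rng.normal(size=(n_units, k))
        G -= G.mean(axis=0, keepdims=True)
        Q, _ = np.linalg.qr(G)
        A = Q.T                              # (k, n_units), A A^T = I, A 1 = 0
        scale = np.sqrt(n_units / k)
        patterns[s] = src @ A * scale + rng.normal(0.0, noise_sd,
                                                   size=(src.shape[0], n_units))
    return SyntheticNeural(patterns=patterns,
                           ground_truth={"kind": "patterns", "noise_sd": noise_sd,
                                         "n_units": n_units, "seed": seed})


def simulate_bold(design: DesignSpec, amplitudes: dict[str, float],
                  noise_sd: float = 1.0, ar: float = 0.3, n_subjects: int = 1,
                  between_subject_sd: float = 0.0, seed: int = 0) -> SyntheticNeural:
    """BOLD-like series: convolved design times planted amplitudes + AR(1) noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    X = design.convolved()
    missing = set(amplitudes) - set(X.columns)
    if missing:
        raise ValueError(f"amplitudes given for unknown regressors: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    mean_signal = sum(a * X[name].to_numpy() for name, a in amplitudes.items())
    series = {}
    n = design.n_scans
    for s in range(n_subjects):
        amp_jitter = rng.normal(0.0, between_subject_sd) if between_subject_sd else 0.0
        eps = rng.normal(0.0, noise_sd, size=n)
        noise = np.empty(n)
        noise[0] = eps[0]
        for t in range(1, n):  # AR(1) innovation filter
            noise[t] = ar * noise[t - 1] + eps[t]
        series[s] = (1.0 + amp_jitter) * mean_signal + noise
    return SyntheticNeural(timeseries=series,
                           ground_truth={"kind": "bold", "amplitudes": amplitudes,
                                         "noise_sd": noise_sd, "ar": ar,
                                         "tr": design.tr, "seed": seed})


def simulate_neural(source: np.ndarray | None = None,
                    design: DesignSpec | None = None,
                    amplitudes: dict[str, float] | None = None,
                    noise_sd: float = 1.0, seed: int = 0,
                    **kwargs) -> SyntheticNeural:
    """Dispatcher: pattern generator when ``source`` is given, BOLD generator
    when ``design`` + ``amplitudes`` are given."""
    if source is not None:
        return simulate_patterns(source, noise_sd=noise_sd, seed=seed, **kwargs)
    if design is not None and amplitudes is not None:
        return simulate_bold(design, amplitudes, noise_sd=noise_sd, seed=seed, **kwargs)
    raise ValueError("supply either source activations or a design + amplitudes")
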