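"""Representational similarity analysis.

A representational dissimilarity matrix (RDM) is 1 minus the Pearson
correlation between every pair of trials' activation patterns (model-layer
nodes or region units/voxels); two RDMs are compared by the Spearman
correlation of their strictly-upper-triangle entries. Group inference
combines a signed-rank test of per-subject correlations against zero with a
permutation test that jointly shuffles rows and columns of one RDM with the
same trial permutation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RDM", "compute_rdm", "rdm_similarity", "rsa_inference", "layerwise_rsa"]


@dataclass
class RDM:
    """Square symmetric trial-by-trial dissimilarity matrix (1 - Pearson r)."""

    matrix: np.ndarray
    trial_ids: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("RDM must be square")
        if len(self.trial_ids) != n:
            raise ValueError("trial_ids length mismatch")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    def subset(self, trial_ids: np.ndarray) -> "RDM":
        pos = {t: i for i, t in enumerate(self.trial_ids.tolist())}
        idx = np.array([pos[t] for t in trial_ids])
        return RDM(self.matrix[np.ix_(idx, idx)], np.asarray(trial_ids), self.source)

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n_trials, k=1)
        return self.matrix[iu]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.matrix, delimiter=",")
        header = {"trial_ids": self.trial_ids.tolist(), "source": self.source}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))


def compute_rdm(patterns: np.ndarray, trial_ids: np.ndarray | None = None,
                source: str = "", zscore_units: bool = False) -> RDM:
    """RDM of a trials x units activation matrix.

    ``zscore_units`` standardizes each unit across trials first (guards
    against scale dominance when units are concatenated across layers).
    """
    P = np.asarray(patterns, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3 or P.shape[1] < 2:
        raise ValueError("patterns must be (>=3 trials, >=2 units)")
    if zscore_units:
        sd = P.std(axis=0)
        P = (P - P.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    row_sd = P.std(axis=1)
    bad = np.flatnonzero(row_sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance pattern rows for trials {bad.tolist()}")
    corr = np.corrcoef(P)
    rdm = 1.0 - corr
    np.fill_diagonal(rdm, 0.0)
    if trial_ids is None:
        trial_ids = np.arange(P.shape[0])
    return RDM(rdm, trial_ids, source)


def rdm_similarity(a: RDM, b: RDM) -> float:
    """Spearman rho between the strict upper triangles of two RDMs.

    Computed on the trial intersection when one source lacks trials."""
    common = [t for t in a.trial_ids.tolist() if t in set(b.trial_ids.tolist())]
    if len(common) < 3:
        raise ValueError("fewer than 3 overlapping trials")
    ua = a.subset(np.asarray(common)).upper()
    ub = b.subset(np.asarray(common)).upper()
    rho, _ = sps.spearmanr(ua, ub)
    return float(rho)


def _permuted(rdm: RDM, perm: np.ndarray) -> RDM:
    return RDM(rdm.matrix[np.ix_(perm, perm)], rdm.trial_ids, rdm.source)


def rsa_inference(subject_rdms: list[RDM], model_rdm: RDM, n_perm: int = 1000,
                  seed: int = 0) -> dict:
    """Group RSA between per-subject pattern RDMs and one model RDM.

    Returns per-subject rhos, the group signed-rank p against zero, and a
    permutation p for the group mean rho built by jointly permuting rows and
    columns of the model RDM (identity ordering included via the +1
    convention).
    """
    if len(subject_rdms) < 2:
        raise ValueError("group inference needs at least 2 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p", RuntimeWarning)
    rhos = np.array([rdm_similarity(s, model_rdm) for s in subject_rdms])
    try:
        _, signed_p = sps.wilcoxon(rhos)
    except ValueError:  # all-zero differences
        signed_p = 1.0
    rng = np.random.default_rng(seed)
    obs = rhos.mean()
    # pre-align each subject with the model RDM once; pre-rank the subject
    # side so each permutation only ranks the shuffled model triangle
    aligned = []
    model_ids = set(model_rdm.trial_ids.tolist())
    for s in subject_rdms:
        common = np.asarray([t for t in s.trial_ids.tolist() if t in model_ids])
        s_upper = s.subset(common).upper()
        sub = model_rdm.subset(common)
        ra = sps.rankdata(s_upper)
        ra = ra - ra.mean()
        ra /= np.linalg.norm(ra)
        iu = np.triu_indices(sub.n_trials, k=1)
        aligned.append((ra, sub.matrix, iu, sub.n_trials))
    null = np.empty(n_perm)
    for k in range(n_perm):
        null_rhos = []
        for ra, mat, iu, n in aligned:
            perm = rng.permutation(n)
            pm = mat[np.ix_(perm, perm)]
            rb = sps.rankdata(pm[iu])
            rb = rb - rb.mean()
            nb = np.linalg.norm(rb)
            null_rhos.append(float(ra @ rb) / nb if nb > 0 else 0.0)
        null[k] = np.mean(null_rhos)
    perm_p = (1 + int(np.sum(null >= obs))) / (1 + n_perm)
    return {"rho": rhos, "mean_rho": float(obs), "signed_rank_p": float(signed_p),
            "permutation_p": float(perm_p), "null": null}


_LAYERS = ("input", "hidden", "final_fc")


def layerwise_rsa(model, X: pd.DataFrame, subject_rdms: list[RDM],
                  which: str = "all", n_perm: int = 1000, seed: int = 0,
                  zscore_units: bool = True,
                  trial_ids: np.ndarray | None = None) -> pd.DataFrame:
    """RSA of each requested model layer (or their concatenation) against
    per-subject pattern RDMs.

    ``which`` is a layer name, ``"all"`` (concatenation of every layer), or
    ``"each"`` (one table row per layer plus the concatenation).
    """
    acts = model.layer_activations(X)
    if trial_ids is None:
        trial_ids = np.arange(len(X))

    def _std(a):
        sd = a.std(axis=0)
        return (a - a.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    sources: dict[str, np.ndarray] = {}
    if which == "each":
        names = list(_LAYERS) + ["all"]
    elif which == "all":
        names = ["all"]
    elif which in _LAYERS:
        names = [which]
    else:
        raise ValueError(f"unknown layer selector {which!r}")
    for name in names:
        if name == "all":
            parts = [_std(acts[l]) if zscore_units else acts[l] for l in _LAYERS]
            sources["all"] = np.concatenate(parts, axis=1)
        else:
            sources[name] = acts[name]

    rows = []
    for name, mat in sources.items():
        rdm = compute_rdm(mat, trial_ids=trial_ids, source=f"layer:{name}",
                          zscore_units=zscore_units and name != "all")
        res = rsa_inference(subject_rdms, rdm, n_perm=n_perm, seed=seed)
        rows.append({"layer": name, "mean_rho": res["mean_rho"],
                     "signed_rank_p": res["signed_rank_p"],
                     "permutation_p": res["permutation_p"]})
    return pd.DataFrame(rows)
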