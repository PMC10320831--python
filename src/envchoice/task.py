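"""Two-stage task structure generation.

The task interleaves *environment choices* (stage 1) — a choice between two
bundles of 20 probabilistic items, each displayed as 20 reward-probability
bars plus a single mean reward magnitude — with *item choices* (stage 2)
between two concrete items drawn from the environment chosen at stage 1.
Each block carries a bonus in a *linked* condition (paid only if the chosen
item's gamble wins) or an *unlinked* condition (paid unconditionally).

The default configuration reproduces the published design: 200 stage-1
trials (400 distinct environments), 200 stage-2 trials, item magnitudes in
[-10, 10], bonuses in [-4, 6], and a gain-gain / loss-loss / mixed valence
mix of 53.5% / 31.5% / 15% realised by exact deterministic allocation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Environment",
    "Block",
    "TaskConfig",
    "TaskDesign",
    "generate_task",
]

N_ITEMS = 20


class ConfigurationError(ValueError):
    """Raised when a generation config violates its declared ranges."""


@dataclass
class Environment:
    """A bundle of 20 probabilistic items offered as a single option.

    Parameters
    ----------
    item_probs : (20,) array
        Per-item reward probabilities in [0, 1].
    item_mags : (20,) array
        Per-item reward magnitudes in currency units; may be negative.
    valence : {"gain", "loss"}
        Whether the displayed mean magnitude is non-negative (gain) or
        negative (loss).
    """

    item_probs: np.ndarray
    item_mags: np.ndarray
    valence: str

    def __post_init__(self) -> None:
        self.item_probs = np.asarray(self.item_probs, dtype=float)
        self.item_mags = np.asarray(self.item_mags, dtype=float)
        if self.item_probs.shape != self.item_mags.shape:
            raise ConfigurationError("item_probs and item_mags must have equal length")
        if np.any(self.item_probs < 0) or np.any(self.item_probs > 1):
            raise ConfigurationError("item probabilities must lie in [0, 1]")
        if self.valence not in ("gain", "loss"):
            raise ConfigurationError(f"unknown valence {self.valence!r}")
        if self.valence == "gain" and self.mean_mag < 0:
            raise ConfigurationError("gain environment with negative mean magnitude")
        if self.valence == "loss" and self.mean_mag >= 0:
            raise ConfigurationError("loss environment with non-negative mean magnitude")

    @property
    def mean_mag(self) -> float:
        """The displayed mean reward magnitude."""
        return float(np.mean(self.item_mags))

    @property
    def mean_prob(self) -> float:
        return float(np.mean(self.item_probs))

    @property
    def ev(self) -> float:
        """Expected value as displayed: mean magnitude x mean probability."""
        return self.mean_mag * self.mean_prob


@dataclass
class Block:
    """One stage-1 trial plus its 0-3 dependent stage-2 trials."""

    env_left: Environment
    env_right: Environment
    bonus: float
    bonus_condition: int  # 1 = linked, 0 = unlinked
    n_item_trials: int
    item_pairs: list[tuple[int, int]]  # indices into the *chosen* environment

    def __post_init__(self) -> None:
        if not 0 <= self.n_item_trials <= 3:
            raise ConfigurationError("n_item_trials must be in 0..3")
        if len(self.item_pairs) != self.n_item_trials:
            raise ConfigurationError("item_pairs length must equal n_item_trials")
        for a, b in self.item_pairs:
            if not (0 <= a < N_ITEMS and 0 <= b < N_ITEMS):
                raise ConfigurationError("item indices must be in 0..19")


@dataclass
class TaskConfig:
    """Generation parameters for :func:`generate_task`.

    The defaults are the published design constants; the stimulus sampling
    distributions (Beta-distributed item probabilities with per-environment
    mean and concentration, antithetic-pair magnitudes) are the package's
    own choices and are fully configurable.
    """

    n_stage1: int = 200
    n_stage2: int = 200
    n_items: int = N_ITEMS
    # valence-pair mix over blocks: (gain-gain, loss-loss, mixed)
    valence_mix: tuple[float, float, float] = (0.535, 0.315, 0.15)
    prob_range: tuple[float, float] = (0.0, 1.0)
    mag_range: tuple[float, float] = (-10.0, 10.0)
    bonus_range: tuple[float, float] = (-4.0, 6.0)
    linked_ratio: float = 0.5
    max_item_trials: int = 3
    # item-probability sampling: per environment, mean ~ U(prob_mean_range),
    # Beta concentration ~ U(prob_concentration_range)
    prob_mean_range: tuple[float, float] = (0.2, 0.8)
    prob_concentration_range: tuple[float, float] = (2.0, 10.0)
    # displayed mean magnitude ~ U over this band inside each valence's half-range
    mag_mean_margin: float = 0.5
    mag_spread: float = 2.5
    # event timing (seconds) for BOLD-style simulation
    stage1_duration: float = 5.0
    stage2_duration: float = 4.0
    iti: float = 2.0

    def validate(self) -> None:
        lo, hi = self.prob_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigurationError("prob_range must be within [0, 1] with lo < hi")
        if self.mag_range[0] >= self.mag_range[1]:
            raise ConfigurationError("mag_range must be increasing")
        if self.bonus_range[0] >= self.bonus_range[1]:
            raise ConfigurationError("bonus_range must be increasing")
        if abs(sum(self.valence_mix) - 1.0) > 1e-9 or min(self.valence_mix) < 0:
            raise ConfigurationError("valence_mix must be non-negative and sum to 1")
        if self.n_stage1 < 0 or self.n_stage2 < 0:
            raise ConfigurationError("trial counts must be non-negative")
        if self.n_stage2 > self.max_item_trials * self.n_stage1:
            raise ConfigurationError("n_stage2 exceeds max_item_trials * n_stage1")
        if not 0.0 <= self.linked_ratio <= 1.0:
            raise ConfigurationError("linked_ratio must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        kwargs = dict(d)
        for k in ("valence_mix", "prob_range", "mag_range", "bonus_range",
                  "prob_mean_range", "prob_concentration_range"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class TaskDesign:
    """An ordered sequence of blocks plus the config and seed that made it."""

    blocks: list[Block]
    config: TaskConfig
    seed: int

    @property
    def n_stage1(self) -> int:
        return len(self.blocks)

    @property
    def n_stage2(self) -> int:
        return sum(b.n_item_trials for b in self.blocks)

    def environments(self) -> list[Environment]:
        out: list[Environment] = []
        for b in self.blocks:
            out.extend((b.env_left, b.env_right))
        return out

    def to_csv(self, path) -> None:
        """Tidy one-row-per-block CSV plus a JSON sidecar with config/seed."""
        import pandas as pd

        rows = []
        for b_idx, b in enumerate(self.blocks):
            row = {"block": b_idx, "bonus": b.bonus,
                   "bonus_condition": b.bonus_condition,
                   "n_item_trials": b.n_item_trials,
                   "item_pairs": ";".join(f"{i}-{j}" for i, j in b.item_pairs),
                   "valence_left": b.env_left.valence,
                   "valence_right": b.env_right.valence,
                   "mean_mag_left": b.env_left.mean_mag,
                   "mean_mag_right": b.env_right.mean_mag}
            for q, env in (("L", b.env_left), ("R", b.env_right)):
                for i, (p, m) in enumerate(zip(env.item_probs, env.item_mags)):
                    row[f"p{q}{i:02d}"] = p
                    row[f"m{q}{i:02d}"] = m
            rows.append(row)
        from pathlib import Path

        path = Path(path)
        pd.DataFrame(rows).to_csv(path, index=False)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"seed": self.seed, "config": self.config.to_dict()}))

    def to_json(self) -> str:
        """Canonical serialization (used for determinism checks)."""
        payload = {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "blocks": [
                {
                    "bonus": b.bonus,
                    "bonus_condition": b.bonus_condition,
                    "n_item_trials": b.n_item_trials,
                    "item_pairs": [list(p) for p in b.item_pairs],
                    "env_left": {
                        "item_probs": b.env_left.item_probs.tolist(),
                        "item_mags": b.env_left.item_mags.tolist(),
                        "valence": b.env_left.valence,
                    },
                    "env_right": {
                        "item_probs": b.env_right.item_probs.tolist(),
                        "item_mags": b.env_right.item_mags.tolist(),
                        "valence": b.env_right.valence,
                    },
                }
                for b in self.blocks
            ],
        }
        return json.dumps(payload, sort_keys=True)


def _allocate_counts(n: int, proportions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder allocation of n slots to proportions."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))  # largest fractional part first
    counts[order[:remainder]] += 1
    return counts


def _allocate_item_trials(n_blocks: int, total: int, max_per: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-block stage-2 trial counts: uniform on {0..max_per}, repaired to the total."""
    if n_blocks == 0:
        return np.zeros(0, dtype=int)
    counts = rng.integers(0, max_per + 1, size=n_blocks)
    while counts.sum() > total:
        idx = rng.choice(np.flatnonzero(counts > 0))
        counts[idx] -= 1
    while counts.sum() < total:
        idx = rng.choice(np.flatnonzero(counts < max_per))
        counts[idx] += 1
    return counts


def _sample_environment(valence: str, config: TaskConfig, rng: np.random.Generator) -> Environment:
    mu = rng.uniform(*config.prob_mean_range)
    kappa = rng.uniform(*config.prob_concentration_range)
    probs = rng.beta(mu * kappa, (1.0 - mu) * kappa, size=config.n_items)
    lo, hi = config.prob_range
    probs = lo + probs * (hi - lo)

    mlo, mhi = config.mag_range
    margin = config.mag_mean_margin
    if valence == "gain":
        mean_mag = rng.uniform(margin, mhi - margin)
    else:
        mean_mag = rng.uniform(mlo + margin, -margin)
    # antithetic pairs m +/- delta keep the mean exact and stay in range
    d = min(mean_mag - mlo, mhi - mean_mag, config.mag_spread)
    deltas = rng.uniform(0.0, d, size=config.n_items // 2)
    mags = np.concatenate([mean_mag + deltas, mean_mag - deltas])
    if config.n_items % 2:
        mags = np.append(mags, mean_mag)
    rng.shuffle(mags)
    return Environment(item_probs=probs, item_mags=mags, valence=valence)


def generate_task(config: TaskConfig | None = None, seed: int = 0) -> TaskDesign:
    """Generate a full task design, deterministic given ``seed``.

    Valence pairs, bonus conditions, and stage-2 trial totals are realised by
    deterministic allocation so the configured proportions hold exactly in
    counts, not just in expectation.
    """
    config = config or TaskConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    n = config.n_stage1
    valence_counts = _allocate_counts(n, np.asarray(config.valence_mix), rng)
    pair_kinds = (["gain-gain"] * valence_counts[0]
                  + ["loss-loss"] * valence_counts[1]
                  + ["mixed"] * valence_counts[2])
    rng.shuffle(pair_kinds)

    linked_counts = _allocate_counts(n, np.asarray([config.linked_ratio,
                                                    1 - config.linked_ratio]), rng)
    conds = np.array([1] * linked_counts[0] + [0] * linked_counts[1])
    rng.shuffle(conds)

    item_trials = _allocate_item_trials(n, config.n_stage2, config.max_item_trials, rng)

    blocks: list[Block] = []
    for kind, cond, n_items_trials in zip(pair_kinds, conds, item_trials):
        if kind == "gain-gain":
            val_l = val_r = "gain"
        elif kind == "loss-loss":
            val_l = val_r = "loss"
        else:
            val_l, val_r = ("gain", "loss") if rng.random() < 0.5 else ("loss", "gain")
        env_l = _sample_environment(val_l, config, rng)
        env_r = _sample_environment(val_r, config, rng)
        bonus = float(rng.uniform(*config.bonus_range))
        # items drawn without replacement within a block
        drawn = rng.choice(config.n_items, size=2 * int(n_items_trials), replace=False)
        pairs = [(int(drawn[2 * t]), int(drawn[2 * t + 1]))
                 for t in range(int(n_items_trials))]
        blocks.append(Block(env_left=env_l, env_right=env_r, bonus=bonus,
                            bonus_condition=int(cond),
                            n_item_trials=int(n_items_trials), item_pairs=pairs))
    return TaskDesign(blocks=blocks, config=config, seed=seed)
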