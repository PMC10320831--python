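"""End-to-end orchestration: simulate -> behavioral GLMs -> model comparison
-> partial DVs -> RSA -> time courses, driven by one config mapping.

Every artifact is written under the run directory and stamped with the seed
and a hash of the config; the same config + seed reproduce identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import agents, features, glm, neural_sim, rsa, timecourse
from .models import compare_models, fit_model
from .task import TaskConfig

logger = logging.getLogger("envchoice")

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Everything a full synthetic replay needs; round-trips through YAML/JSON."""

    seed: int = 0
    n_subjects: int = 8
    task: dict = dataclasses.field(default_factory=dict)
    agent: dict = dataclasses.field(default_factory=lambda: {
        "model_id": "mvs",
        "params": {"rho": 1.0, "sigma": 0.0, "b1": 0.3, "b2": 3.0,
                   "b5": 0.15, "b6": 0.2},
    })
    models: list = dataclasses.field(default_factory=lambda: ["cnn", "glm"])
    folds: int = 20
    model_kwargs: dict = dataclasses.field(default_factory=lambda: {
        "cnn": {"n_hidden": 32, "n_epochs": 300}})
    rsa_n_perm: int = 500
    rsa_n_units: int = 40
    rsa_noise_sd: float = 1.0
    out_dir: str = "envchoice_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _stamp(cfg: RunConfig, out: Path) -> None:
    (out / "run_config.json").write_text(json.dumps(
        {"config": cfg.to_dict(), "config_hash": cfg.config_hash()}, indent=1))


def run_pipeline(config: RunConfig | dict) -> Path:
    """Execute the full synthetic replay; returns the run directory."""
    cfg = RunConfig.from_dict(config) if isinstance(config, dict) else config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _stamp(cfg, out)

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        task_cfg = TaskConfig.from_dict(cfg.task) if cfg.task else TaskConfig()
        dataset = agents.simulate_cohort(cfg.agent, cfg.n_subjects,
                                         seed=cfg.seed, task_config=task_cfg)
        dataset.to_csv(out / "trials.csv")

        stage("behavioral_glm")
        g1 = glm.fit_glm1(dataset, stage=1)
        g1.group.to_csv(out / "glm1_group.csv", index=False)
        g1.coefficients.to_csv(out / "glm1_subjects.csv")
        g2 = glm.fit_glm2(dataset)
        g2.group.to_csv(out / "glm2_group.csv", index=False)

        stage("fit_compare")
        fits = []
        for mid in cfg.models:
            kw = cfg.model_kwargs.get(mid, {})
            fit = fit_model(mid, dataset, folds=cfg.folds, seed=cfg.seed,
                            keep_models=(mid == "cnn"), **kw)
            fit.to_json(out / f"fit_{mid}.json")
            fits.append(fit)
        comparison = compare_models(fits)
        comparison["table"].to_csv(out / "model_comparison.csv", index=False)
        comparison["pairwise"].to_csv(out / "model_comparison_pairwise.csv",
                                      index=False)

        cnn_fit = next((f for f in fits if f.model_id == "cnn" and f.fold_models), None)
        df1 = dataset.stage(1)
        if cnn_fit is not None:
            stage("partial_dv")
            cnn = cnn_fit.fold_models[0]
            table = features.partial_dv_table(cnn, df1)
            table.to_csv(out / "partial_dv.csv", index=False)
            features.moment_correlations(table).to_csv(
                out / "moment_correlations.csv", index=False)

            stage("rsa")
            acts = cnn.layer_activations(df1)
            syn = neural_sim.simulate_patterns(
                acts["hidden"], n_units=cfg.rsa_n_units,
                noise_sd=cfg.rsa_noise_sd, n_subjects=cfg.n_subjects,
                seed=cfg.seed + 1)
            subject_rdms = [rsa.compute_rdm(p, source=f"subject{s}")
                            for s, p in syn.patterns.items()]
            layer_table = rsa.layerwise_rsa(cnn, df1, subject_rdms, which="each",
                                            n_perm=cfg.rsa_n_perm, seed=cfg.seed + 2)
            layer_table.to_csv(out / "rsa_layers.csv", index=False)

            stage("timecourse")
            series = {}
            for s in range(cfg.n_subjects):
                spec, _ = timecourse.build_design(dataset, glm=3, dv_model=cnn,
                                                  subject=s, stage=1)
                syn_bold = neural_sim.simulate_bold(
                    spec, {"delta_dv": 1.0}, noise_sd=0.5, seed=cfg.seed + 10 + s)
                series[s] = syn_bold.timeseries[0]
            tc = timecourse.beta_timecourse(series, dataset, glm=3, dv_model=cnn,
                                            stage=1)
            peak = timecourse.loso_peak(tc, "delta_dv")
            pd.DataFrame({
                "time": tc.times,
                "mean_beta": tc.group_mean("delta_dv"),
                "sem_beta": tc.group_sem("delta_dv"),
            }).to_csv(out / "timecourse_delta_dv.csv", index=False)
            (out / "timecourse_peak.json").write_text(json.dumps({
                "regressor": peak.regressor, "peak_time": peak.peak_time,
                "t": peak.t, "df": peak.df, "p": peak.p, "bf10": peak.bf10},
                indent=1))
            _plot_timecourse(tc, out / "timecourse_delta_dv.png")
    except Exception as e:
        raise RuntimeError(f"pipeline failed (partial outputs kept in {out})") from e
    return out


def _plot_timecourse(tc, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is optional
        return
    fig, ax = plt.subplots(figsize=(5, 3))
    m = tc.group_mean("delta_dv")
    s = tc.group_sem("delta_dv")
    ax.plot(tc.times, m, color="tab:blue")
    ax.fill_between(tc.times, m - s, m + s, alpha=0.3, color="tab:blue")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel(r"$\Delta$DV beta")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
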