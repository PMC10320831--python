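"""ROI time-course statistics on BOLD-like signals.

Implements the event-related machinery used around the choice models:
canonical double-gamma HRF convolution of parametric event regressors
(GLM3-GLM6 designs), per-subject beta time courses (epoched at stimulus
onset, cubic-spline upsampled 10x, OLS at each peristimulus timepoint),
leave-one-subject-out (LOSO) peak extraction inside an FWHM window defined
by the held-out group curve, PPI design construction, and one-sample
t-tests supplemented by JZS Bayes factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import CubicSpline

from .datasets import ChoiceDataset

__all__ = [
    "double_gamma_hrf", "trial_regressors", "DesignSpec", "build_design",
    "BetaTimecourse", "beta_timecourse", "PeakStat", "loso_peak",
    "ppi_design", "bf_ttest",
]

TR_DEFAULT = 1.6


def double_gamma_hrf(dt: float, duration: float = 32.0, peak_delay: float = 6.0,
                     undershoot_delay: float = 16.0, peak_disp: float = 1.0,
                     undershoot_disp: float = 1.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``dt`` seconds.

    Peak at ~6 s, undershoot at ~16 s, normalized to unit peak height.
    """
    t = np.arange(0, duration, dt)
    peak = sps.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = sps.gamma.pdf(t, undershoot_delay / undershoot_disp,
                          scale=undershoot_disp)
    h = peak - undershoot_ratio * under
    return h / h.max()


# ---------------------------------------------------------------------------
# per-trial parametric regressor values for GLM designs 3-6

def _delta_dv(model, df: pd.DataFrame) -> np.ndarray:
    """Chosen-minus-unchosen decision-value difference per trial."""
    dv = model.decision_values(df)
    choice = df["choice"].to_numpy(int)
    n = np.arange(len(df))
    return dv[n, choice] - dv[n, 1 - choice]


def _dv_bonus_split(model, df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Basic / linked-bonus / unlinked-bonus decomposition of the DV.

    The basic term removes the bonus entirely; the bonus contribution is the
    full-minus-basic DV computed with the condition forced to linked, booked
    to the linked or unlinked regressor according to the trial's actual
    condition.
    """
    basic_df = df.copy()
    basic_df["bonus"] = 0.0
    basic = _delta_dv(model, basic_df)
    linked_df = df.copy()
    linked_df["bonus_condition"] = 1
    full_linked = _delta_dv(model, linked_df)
    basic_linked_df = linked_df.copy()
    basic_linked_df["bonus"] = 0.0
    bonus_part = full_linked - _delta_dv(model, basic_linked_df)
    is_linked = df["bonus_condition"].to_numpy() == 1
    return {
        "dv_basic": basic,
        "dv_linked_bonus": np.where(is_linked, bonus_part, 0.0),
        "dv_unlinked_bonus": np.where(~is_linked, bonus_part, 0.0),
    }


def trial_regressors(df: pd.DataFrame, glm: int, dv_model=None) -> pd.DataFrame:
    """Per-trial parametric regressor values for one stage's trials.

    GLM3: the chosen-unchosen DV difference. GLM4: the three-way bonus
    split of the DV. GLM5: GLM4 plus the first-item-trial indicator (+1/-1)
    and its interaction with the linked-bonus DV. GLM6: DV difference plus
    EV-based salience (sum of absolute option EVs) and EV-based DV sum.
    """
    if glm in (3, 4, 5) and dv_model is None:
        raise ValueError(f"GLM{glm} requires a fitted decision-value model")
    if glm == 3:
        return pd.DataFrame({"delta_dv": _delta_dv(dv_model, df)})
    if glm == 4:
        return pd.DataFrame(_dv_bonus_split(dv_model, df))
    if glm == 5:
        out = pd.DataFrame(_dv_bonus_split(dv_model, df))
        first = np.where(df["trial_in_block"].to_numpy() == 1, 1.0, -1.0)
        out["first_trial"] = first
        out["first_x_linked_bonus"] = first * out["dv_linked_bonus"]
        return out
    if glm == 6:
        ev_l = (df["mag_left"] * df["prob_left"]).to_numpy()
        ev_r = (df["mag_right"] * df["prob_right"]).to_numpy()
        if dv_model is not None:
            ddv = _delta_dv(dv_model, df)
        else:
            choice = df["choice"].to_numpy(int)
            ev = np.column_stack([ev_l, ev_r])
            n = np.arange(len(df))
            ddv = ev[n, choice] - ev[n, 1 - choice]
        return pd.DataFrame({"delta_dv": ddv,
                             "salience": np.abs(ev_l) + np.abs(ev_r),
                             "dv_sum": ev_l + ev_r})
    raise ValueError("glm must be one of 3, 4, 5, 6")


@dataclass
class DesignSpec:
    """Named event regressors (onsets + mean-centered values) at a TR grid."""

    regressors: dict[str, tuple[np.ndarray, np.ndarray]]
    tr: float
    n_scans: int
    hrf_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        duration = self.n_scans * self.tr
        for name, (onsets, values) in self.regressors.items():
            onsets = np.asarray(onsets, float)
            if np.any(onsets < 0) or np.any(onsets >= duration):
                raise ValueError(f"regressor {name!r} has onsets outside the run")
        if len(set(self.regressors)) != len(self.regressors):
            raise ValueError("regressor names must be unique")

    def convolved(self, oversample: int = 10) -> pd.DataFrame:
        """HRF-convolved design matrix sampled at the TR grid."""
        dt = self.tr / oversample
        n_hi = self.n_scans * oversample
        hrf = double_gamma_hrf(dt, **self.hrf_kwargs)
        cols = {}
        for name, (onsets, values) in self.regressors.items():
            stick = np.zeros(n_hi)
            idx = np.round(np.asarray(onsets, float) / dt).astype(int)
            np.add.at(stick, np.clip(idx, 0, n_hi - 1), values)
            conv = np.convolve(stick, hrf)[:n_hi]
            cols[name] = conv[::oversample]
        return pd.DataFrame(cols)


def build_design(dataset: ChoiceDataset, glm: int, dv_model=None,
                 subject: int = 0, stage: int = 1, tr: float = TR_DEFAULT,
                 n_scans: int | None = None, mean_center: bool = True,
                 hrf_kwargs: dict | None = None) -> tuple[DesignSpec, pd.DataFrame]:
    """Event design + convolved matrix for one subject's run."""
    df = dataset.stage(stage)
    df = df[df["subject"] == subject].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"subject {subject} has no stage-{stage} trials")
    vals = trial_regressors(df, glm, dv_model)
    onsets = df["onset"].to_numpy(float)
    if n_scans is None:
        n_scans = int(np.ceil((onsets.max() + 30.0) / tr))
    regs = {}
    for name in vals.columns:
        v = vals[name].to_numpy(float)
        if mean_center:
            v = v - v.mean()
        regs[name] = (onsets, v)
    spec = DesignSpec(regressors=regs, tr=tr, n_scans=n_scans,
                      hrf_kwargs=hrf_kwargs or {})
    return spec, spec.convolved()


# ---------------------------------------------------------------------------
# beta time courses

@dataclass
class BetaTimecourse:
    """Subject x regressor x peristimulus-timepoint beta array."""

    betas: np.ndarray
    times: np.ndarray
    regressor_names: list[str]
    subjects: list[int]

    def group_mean(self, regressor: str) -> np.ndarray:
        return self.betas[:, self._idx(regressor), :].mean(axis=0)

    def group_sem(self, regressor: str) -> np.ndarray:
        return sps.sem(self.betas[:, self._idx(regressor), :], axis=0)

    def _idx(self, regressor: str) -> int:
        return self.regressor_names.index(regressor)


def beta_timecourse(series_by_subject: dict[int, np.ndarray],
                    dataset: ChoiceDataset, glm: int, dv_model=None,
                    stage: int = 1, tr: float = TR_DEFAULT,
                    window: tuple[float, float] = (-2.0, 14.0),
                    upsample: int = 10) -> BetaTimecourse:
    """Per-subject epoched beta series for each regressor of a GLM design.

    The ROI series is upsampled ``upsample``-fold by cubic spline, epoched
    around each trial onset, and the activity at every upsampled timepoint
    is regressed (OLS with intercept) on the trial-level regressors.
    """
    subjects = sorted(series_by_subject)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    dt = tr / upsample
    rel_times = np.arange(window[0], window[1] + dt / 2, dt)
    all_betas = []
    names = None
    for s in subjects:
        series = np.asarray(series_by_subject[s], float)
        t_scan = np.arange(len(series)) * tr
        spline = CubicSpline(t_scan, series)
        df = dataset.stage(stage)
        df = df[df["subject"] == s].reset_index(drop=True)
        vals = trial_regressors(df, glm, dv_model)
        names = list(vals.columns)
        onsets = df["onset"].to_numpy(float)
        sample_t = onsets[:, None] + rel_times[None, :]
        run_end = t_scan[-1]
        if np.any(sample_t > run_end):
            warnings.warn("epochs extend past run end; samples truncated to the "
                          "last scan", RuntimeWarning)
            sample_t = np.minimum(sample_t, run_end)
        sample_t = np.maximum(sample_t, 0.0)
        Y = spline(sample_t)                      # (n_trials, n_timepoints)
        X = np.column_stack([np.ones(len(df)), vals.to_numpy(float)])
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)  # (1+k, n_timepoints)
        all_betas.append(B[1:, :])
    return BetaTimecourse(betas=np.stack(all_betas), times=rel_times,
                          regressor_names=names, subjects=subjects)


@dataclass
class PeakStat:
    regressor: str
    peak_time: float
    peaks: np.ndarray        # per-subject LOSO-extracted peak betas
    t: float
    df: int
    p: float
    bf10: float


def loso_peak(tc: BetaTimecourse, regressor: str,
              rule: str = "heldout_argmax") -> PeakStat:
    """Leave-one-subject-out peak extraction with FWHM windowing.

    The full group curve defines the peak (largest |beta|) and its FWHM
    window; each subject's peak beta is read at the extremum position of the
    group curve recomputed without that subject, restricted to the window
    (``rule="own_argmax"`` instead uses the subject's own extremum within
    the window). Peaks are tested against zero by a one-sample t-test plus
    a JZS Bayes factor.
    """
    j = tc._idx(regressor)
    curves = tc.betas[:, j, :]                    # (n_subjects, n_timepoints)
    group = curves.mean(axis=0)
    if np.allclose(group, 0.0):
        raise ValueError("flat group curve: no peak definable")
    peak_idx = int(np.argmax(np.abs(group)))
    half = np.abs(group[peak_idx]) / 2.0
    inside = np.abs(group) >= half
    lo = peak_idx
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi < len(group) - 1 and inside[hi + 1]:
        hi += 1
    window = slice(lo, hi + 1)

    n = curves.shape[0]
    peaks = np.empty(n)
    for s in range(n):
        held_out = np.delete(curves, s, axis=0).mean(axis=0)
        if rule == "heldout_argmax":
            pos = lo + int(np.argmax(np.abs(held_out[window])))
        elif rule == "own_argmax":
            pos = lo + int(np.argmax(np.abs(curves[s, window])))
        else:
            raise ValueError(f"unknown rule {rule!r}")
        peaks[s] = curves[s, pos]
    res = bf_ttest(peaks)
    return PeakStat(regressor=regressor, peak_time=float(tc.times[peak_idx]),
                    peaks=peaks, t=res["t"], df=n - 1, p=res["p"],
                    bf10=res["bf10"])


def ppi_design(stage_indicator: np.ndarray, phys1: np.ndarray,
               phys2: np.ndarray) -> pd.DataFrame:
    """Five-column PPI design: stage dummy, two physiological series, and
    their stage interactions (physiological series mean-centered first)."""
    stage = np.asarray(stage_indicator, float)
    p1 = np.asarray(phys1, float) - np.mean(phys1)
    p2 = np.asarray(phys2, float) - np.mean(phys2)
    if stage.std() == 0:
        warnings.warn("constant stage indicator: interaction columns are "
                      "collinear with the physiological regressors", RuntimeWarning)
    return pd.DataFrame({
        "stage": stage, "phys1": p1, "phys2": p2,
        "stage_x_phys1": stage * p1, "stage_x_phys2": stage * p2,
    })


def bf_ttest(values: np.ndarray, mu: float = 0.0) -> dict[str, float]:
    """One-sample t-test plus JZS Bayes factor (Cauchy scale sqrt(2)/2)."""
    import pingouin as pg

    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    t, p = sps.ttest_1samp(values, mu)
    bf10 = float(pg.bayesfactor_ttest(float(t), values.size, paired=True))
    return {"t": float(t), "p": float(p), "bf10": bf10, "df": values.size - 1}
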