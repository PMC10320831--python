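import numpy as np
import pytest

import envchoice as ec
from envchoice.neural_sim import simulate_bold
from envchoice.timecourse import (
    BetaTimecourse, DesignSpec, bf_ttest, beta_timecourse, build_design,
    double_gamma_hrf, loso_peak, ppi_design, trial_regressors,
)


@pytest.fixture(scope="module")
def glm_dataset(small_task):
    return ec.simulate_agent(
        small_task, "glm",
        {"b0": 0.0, "b1": 0.2, "b2": 2.0, "b5": 0.4, "b6": 0.3},
        seed=50, n_subjects=4)


@pytest.fixture(scope="module")
def dv_model():
    return ec.make_model("glm", params={"b0": 0.0, "b1": 0.2, "b2": 2.0,
                                        "b5": 0.4, "b6": 0.3})


class TestHrf:
    def test_peak_near_six_seconds(self):
        dt = 0.1
        h = double_gamma_hrf(dt)
        assert np.argmax(h) * dt == pytest.approx(5.0, abs=1.5)
        assert h.max() == pytest.approx(1.0)

    def test_undershoot_present(self):
        h = double_gamma_hrf(0.1)
        assert h.min() < 0

    def test_impulse_response_is_hrf(self):
        spec = DesignSpec(regressors={"x": (np.array([0.0]), np.array([1.0]))},
                          tr=1.6, n_scans=20)
        X = spec.convolved(oversample=10)
        h = double_gamma_hrf(0.16)
        np.testing.assert_allclose(X["x"].to_numpy()[:len(h[::10])],
                                   h[::10][:20], atol=1e-12)


class TestDesigns:
    def test_glm4_has_three_way_bonus_split(self, glm_dataset, dv_model):
        spec, X = build_design(glm_dataset, glm=4, dv_model=dv_model,
                               subject=0, stage=1)
        assert list(X.columns) == ["dv_basic", "dv_linked_bonus",
                                   "dv_unlinked_bonus"]

    def test_glm5_adds_first_trial_terms(self, glm_dataset, dv_model):
        spec, X = build_design(glm_dataset, glm=5, dv_model=dv_model,
                               subject=0, stage=2)
        assert list(X.columns) == ["dv_basic", "dv_linked_bonus",
                                   "dv_unlinked_bonus", "first_trial",
                                   "first_x_linked_bonus"]

    def test_glm6_salience_and_dv_sum_are_ev_based(self, glm_dataset):
        df = glm_dataset.stage(1)
        vals = trial_regressors(df, glm=6)
        ev_l = (df["mag_left"] * df["prob_left"]).to_numpy()
        ev_r = (df["mag_right"] * df["prob_right"]).to_numpy()
        np.testing.assert_allclose(vals["salience"], np.abs(ev_l) + np.abs(ev_r))
        np.testing.assert_allclose(vals["dv_sum"], ev_l + ev_r)

    def test_zero_bonus_dataset_zeroes_bonus_regressors(self, glm_dataset,
                                                        dv_model):
        ds = ec.ChoiceDataset(trials=glm_dataset.trials.assign(bonus=0.0),
                              n_subjects=glm_dataset.n_subjects)
        vals = trial_regressors(ds.stage(1), glm=4, dv_model=dv_model)
        np.testing.assert_allclose(vals["dv_linked_bonus"], 0.0, atol=1e-12)
        np.testing.assert_allclose(vals["dv_unlinked_bonus"], 0.0, atol=1e-12)

    def test_missing_dv_model_rejected(self, glm_dataset):
        with pytest.raises(ValueError):
            trial_regressors(glm_dataset.stage(1), glm=3)


class TestBetaTimecourse:
    def test_planted_amplitude_recovered_at_peak(self, glm_dataset, dv_model):
        series = {}
        for s in range(4):
            spec, _ = build_design(glm_dataset, glm=3, dv_model=dv_model,
                                   subject=s, stage=1)
            syn = simulate_bold(spec, {"delta_dv": 2.0}, noise_sd=0.0,
                                ar=0.0, seed=60 + s)
            series[s] = syn.timeseries[0]
        tc = beta_timecourse(series, glm_dataset, glm=3, dv_model=dv_model,
                             stage=1)
        peak_beta = np.max(np.abs(tc.group_mean("delta_dv")))
        # HRF is unit-peak so the noiseless beta peak ~ planted amplitude
        assert peak_beta == pytest.approx(2.0, rel=0.15)

    def test_pure_noise_betas_cover_zero(self, glm_dataset, dv_model):
        rng = np.random.default_rng(61)
        series = {s: rng.normal(size=1400) for s in range(4)}
        tc = beta_timecourse(series, glm_dataset, glm=3, dv_model=dv_model,
                             stage=1)
        m = tc.group_mean("delta_dv")
        sem = tc.group_sem("delta_dv")
        frac_cover = np.mean(np.abs(m) < 3 * sem)
        assert frac_cover > 0.9

    def test_constant_series_gives_zero_slopes(self, glm_dataset, dv_model):
        series = {s: np.full(1400, 5.0) for s in range(4)}
        tc = beta_timecourse(series, glm_dataset, glm=3, dv_model=dv_model,
                             stage=1)
        np.testing.assert_allclose(tc.betas, 0.0, atol=1e-8)


class TestLosoPeak:
    @staticmethod
    def _bump_tc(center=6.0, amp=1.0, jitter=None, n_subjects=6):
        times = np.arange(-2, 14.01, 0.16)
        curves = []
        for s in range(n_subjects):
            a = amp if jitter is None else amp + jitter[s]
            curves.append(a * np.exp(-0.5 * ((times - center) / 1.5) ** 2))
        betas = np.stack(curves)[:, None, :]
        return BetaTimecourse(betas=betas, times=times,
                              regressor_names=["delta_dv"],
                              subjects=list(range(n_subjects)))

    def test_identical_bumps_extract_center(self):
        tc = self._bump_tc()
        stat = loso_peak(tc, "delta_dv")
        assert stat.peak_time == pytest.approx(6.0, abs=0.2)
        np.testing.assert_allclose(stat.peaks, 1.0, rtol=1e-9)
        assert stat.df == 5

    def test_flat_curve_raises(self):
        tc = self._bump_tc(amp=0.0)
        with pytest.raises(ValueError):
            loso_peak(tc, "delta_dv")

    def test_sign_flip_negates_peak_keeps_t(self):
        jit = np.random.default_rng(62).normal(0, 0.1, 6)
        tc = self._bump_tc(jitter=jit)
        tc_neg = BetaTimecourse(betas=-tc.betas, times=tc.times,
                                regressor_names=tc.regressor_names,
                                subjects=tc.subjects)
        s1 = loso_peak(tc, "delta_dv")
        s2 = loso_peak(tc_neg, "delta_dv")
        np.testing.assert_allclose(s2.peaks, -s1.peaks, rtol=1e-9)
        assert abs(s2.t) == pytest.approx(abs(s1.t), rel=1e-9)

    def test_loso_invariant_for_identical_subjects(self):
        tc = self._bump_tc()
        s_ho = loso_peak(tc, "delta_dv", rule="heldout_argmax")
        s_own = loso_peak(tc, "delta_dv", rule="own_argmax")
        np.testing.assert_allclose(s_ho.peaks, s_own.peaks, rtol=1e-12)


class TestPpi:
    def test_five_columns(self):
        rng = np.random.default_rng(63)
        X = ppi_design(rng.integers(0, 2, 100), rng.normal(size=100),
                       rng.normal(size=100))
        assert X.shape == (100, 5)
        assert list(X.columns) == ["stage", "phys1", "phys2",
                                   "stage_x_phys1", "stage_x_phys2"]

    def test_constant_stage_flags_collinearity(self):
        rng = np.random.default_rng(64)
        with pytest.warns(RuntimeWarning):
            X = ppi_design(np.ones(50), rng.normal(size=50), rng.normal(size=50))
        np.testing.assert_allclose(X["stage_x_phys1"], X["phys1"])

    def test_planted_stage_coupling_recovered(self):
        rng = np.random.default_rng(65)
        n = 600
        stage = (np.arange(n) % 10 < 5).astype(float)
        phys1 = rng.normal(size=n)
        phys2 = rng.normal(size=n)
        # seed activity couples with phys1 only during stage 1
        seed_ts = 0.8 * stage * phys1 + 0.1 * phys2 + rng.normal(0, 0.3, n)
        X = ppi_design(stage, phys1, phys2)
        Xm = np.column_stack([np.ones(n), X.to_numpy()])
        beta, *_ = np.linalg.lstsq(Xm, seed_ts, rcond=None)
        assert beta[4] > 0.4   # stage x phys1
        assert abs(beta[5]) < 0.2


class TestBfTtest:
    def test_null_t_favors_null(self):
        vals = np.array([-1.0, 1.0, -0.5, 0.5])
        res = bf_ttest(vals)
        assert res["t"] == pytest.approx(0.0)
        assert res["bf10"] < 1

    def test_large_effect_gives_strong_evidence(self):
        rng = np.random.default_rng(66)
        vals = rng.normal(1.0, 1.0, 24)  # d ~ 1
        res = bf_ttest(vals)
        assert res["bf10"] > 10

    def test_monotone_in_t_at_fixed_n(self):
        import pingouin as pg
        bfs = [float(pg.bayesfactor_ttest(t, 24, paired=True))
               for t in np.linspace(0, 6, 13)]
        assert np.all(np.diff(bfs) > 0)
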