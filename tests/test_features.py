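import numpy as np
import pytest
from scipy import stats as sps

import envchoice as ec
from envchoice.features import (
    compare_dependent_correlations, moment_correlations, partial_dv,
    partial_dv_table,
)
from envchoice.models.networks import CnnChoiceModel


class TestPartialDv:
    def test_single_detector_partial_equals_full(self, mvs_dataset):
        df = mvs_dataset.stage(1)
        m = ec.make_model("cnn", n_detectors=1, n_hidden=8, n_epochs=80,
                          seed=0).fit(df)
        full = m.decision_values(df)
        part = m.partial_decision_values(df, 0)
        np.testing.assert_allclose(part, full, rtol=1e-10)

    def test_zeroing_all_detectors_gives_bias_only_pass(self, trained_cnn,
                                                        mvs_dataset):
        df = mvs_dataset.stage(1)
        base = trained_cnn.baseline_decision_values(df)
        # zero every detector's weights/biases: partial DV of any detector
        # must equal the bias-only pass
        import copy
        m = copy.deepcopy(trained_cnn)
        m.W1_ = np.zeros_like(m.W1_)
        m.b1_ = np.zeros_like(m.b1_)
        np.testing.assert_allclose(m.partial_decision_values(df, 0),
                                   m.baseline_decision_values(df), rtol=1e-10)

    def test_linear_network_partial_dvs_are_additive(self, mvs_dataset):
        """With the hidden nonlinearity inactive (all-positive preactivations
        impossible to guarantee, so use an identity-like construction), the
        partial DVs of a linear readout decompose the full DV exactly."""
        df = mvs_dataset.stage(1)
        rng = np.random.default_rng(0)
        F, H = 3, 5
        w = CnnChoiceModel.random_weights(n_detectors=F, n_hidden=H, seed=1)
        w["W2"] = np.abs(w["W2"]) * 0.01  # keep preactivations positive
        w["b2"] = np.full(H, 10.0)        # push ReLU into its linear region
        m = CnnChoiceModel(weights=w, standardize=False)
        full = m.decision_values(df)
        base = m.baseline_decision_values(df)
        total = sum(m.partial_decision_values(df, d) for d in range(F))
        np.testing.assert_allclose(total - (F - 1) * base, full, rtol=1e-6)

    def test_out_of_range_detector_raises(self, trained_cnn, mvs_dataset):
        with pytest.raises(IndexError):
            trained_cnn.partial_decision_values(mvs_dataset.stage(1), 99)

    def test_table_shape(self, trained_cnn, mvs_dataset):
        df = mvs_dataset.stage(1)
        table = partial_dv_table(trained_cnn, df)
        assert len(table) == len(df)
        assert sum(c.startswith("partial_dv_") for c in table.columns) == 4


class TestMomentCorrelations:
    def test_exact_copy_of_mean_diff_has_r1(self, trained_cnn, mvs_dataset):
        table = partial_dv_table(trained_cnn, mvs_dataset.stage(1))
        table["partial_dv_0"] = table["mean_diff"]
        out = moment_correlations(table)
        row = out[(out.detector == 0) & (out.moment == "mean_diff")].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_sign_flip_negates_r(self, trained_cnn, mvs_dataset):
        table = partial_dv_table(trained_cnn, mvs_dataset.stage(1))
        out1 = moment_correlations(table)
        for d in range(4):
            table[f"partial_dv_{d}"] *= -1
        out2 = moment_correlations(table)
        np.testing.assert_allclose(out2["r"], -out1["r"], rtol=1e-10)

    def test_independent_noise_is_uncorrelated(self, trained_cnn, mvs_dataset):
        rng = np.random.default_rng(3)
        table = partial_dv_table(trained_cnn, mvs_dataset.stage(1))
        ps = []
        for rep in range(200):
            noise = rng.normal(size=len(table))
            r, p = sps.pearsonr(noise, table["mean_diff"])
            ps.append(p)
        # p-values approximately uniform: KS test does not reject
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_mvs_agent_variance_detector_recovery(self):
        """On variance-seeking agent data, some detector's partial DV tracks
        the variance difference positively (directional recovery)."""
        hits = 0
        for seed in range(3):
            cfg = ec.TaskConfig(n_stage1=120, n_stage2=0)
            ds = ec.simulate_cohort(
                {"model_id": "mvs",
                 "params": {"rho": 2.0, "sigma": 0.0, "b1": 0.2, "b2": 5.0,
                            "b5": 0.1, "b6": 0.1}},
                n_subjects=4, seed=100 + seed, task_config=cfg)
            df = ds.stage(1)
            cnn = ec.make_model("cnn", n_hidden=16, n_epochs=150,
                                seed=seed).fit(df)
            out = moment_correlations(partial_dv_table(cnn, df))
            var_rows = out[out.moment == "var_diff"]
            if (var_rows["r"] > 0.05).any():
                hits += 1
        assert hits >= 2


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        z, p = compare_dependent_correlations(0.4, 0.4, 0.3, 50)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, _ = compare_dependent_correlations(0.5, 0.3, 0.2, 100)
        z2, _ = compare_dependent_correlations(0.3, 0.5, 0.2, 100)
        assert z1 == pytest.approx(-z2)

    def test_worked_triple_matches_independent_formula(self):
        r1, r2, r12, n = 0.5, 0.3, 0.2, 100
        # independent evaluation of the Fisher-transform formula
        z1 = 0.5 * np.log((1 + r1) / (1 - r1))
        z2 = 0.5 * np.log((1 + r2) / (1 - r2))
        rm2 = (r1 ** 2 + r2 ** 2) / 2
        f = (1 - r12) / (2 * (1 - rm2))
        h = (1 - f * rm2) / (1 - rm2)
        expected = (z1 - z2) * np.sqrt((n - 3) / (2 * (1 - r12) * h))
        z, p = compare_dependent_correlations(r1, r2, r12, n)
        assert z == pytest.approx(expected, rel=1e-12)
        assert 0 < p < 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(1.0, 0.3, 0.2, 100)
        with pytest.raises(ValueError):
            compare_dependent_correlations(0.5, 0.3, 0.2, 3)
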