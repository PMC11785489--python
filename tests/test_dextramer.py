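"""Dextramer background normalization, binder calling, antigen-level association."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import tcrfate as tf


def constant_covariate_panel(counts, nc=2):
    """Panel where all technical covariates are identical across cells, so
    every cell shares one expected background count."""
    n = len(counts)
    df = pd.DataFrame(
        {
            "DEX1": np.asarray(counts, dtype=int),
            "NC1": np.full(n, nc),
        }
    )
    cov = pd.DataFrame(
        {
            "tcr_exp": np.full(n, 2.0),
            "cd3_exp": np.zeros(n),
            "cd8_exp": np.zeros(n),
            "donor_id": ["D00"] * n,
        }
    )
    return tf.DextramerPanel(counts=df, negative_controls=["NC1"], covariates=cov)


@pytest.fixture(scope="module")
def spiked():
    cfg = tf.SimConfig(n_donors=4, cells_per_donor=2500)
    panel, truth = tf.simulate_dextramer(cfg, seed=5)
    return panel, truth


class TestPanelValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            constant_covariate_panel([-1, 2, 3])

    def test_no_negative_controls_rejected(self):
        df = pd.DataFrame({"DEX1": [1, 2]})
        cov = pd.DataFrame(
            {"tcr_exp": [1.0, 1.0], "cd3_exp": [0.0, 0.0], "cd8_exp": [0.0, 0.0],
             "donor_id": ["D", "D"]}
        )
        with pytest.raises(ValueError):
            tf.DextramerPanel(counts=df, negative_controls=[], covariates=cov)

    def test_missing_covariate_rejected(self):
        df = pd.DataFrame({"DEX1": [1, 2], "NC1": [1, 1]})
        cov = pd.DataFrame({"tcr_exp": [1.0, 1.0], "donor_id": ["D", "D"]})
        with pytest.raises(ValueError, match="covariates"):
            tf.DextramerPanel(counts=df, negative_controls=["NC1"], covariates=cov)


class TestBackgroundFit:
    def test_negative_control_target_rejected(self, spiked):
        panel, _ = spiked
        with pytest.raises(ValueError):
            tf.fit_background(panel, "NC1")

    def test_all_zero_outcome_rejected(self):
        panel = constant_covariate_panel(np.zeros(50, dtype=int))
        with pytest.raises(ValueError):
            tf.fit_background(panel, "DEX1")

    def test_coefficient_recovery(self):
        """Fitting the background regression on binder-free counts simulated
        from its own model recovers the generating coefficients within 2 se
        (true values: 0.05 per negative control, 0.10 TCR, 0.05 CD3/CD8)."""
        cfg = tf.SimConfig(n_donors=4, cells_per_donor=5000, binder_fraction=0.0)
        panel, _ = tf.simulate_dextramer(cfg, seed=9)
        fit = tf.fit_background(panel, "DEX1")
        assert fit.converged
        # at n=20,000 the coefficients are tight; 0.02 absolute (~several se)
        for name, true in [
            ("nc_NC1", 0.05), ("nc_NC2", 0.05), ("nc_NC3", 0.05),
            ("tcr_exp", 0.10), ("cd3_exp", 0.05), ("cd8_exp", 0.05),
        ]:
            assert fit.params[name] == pytest.approx(true, abs=0.02)
        assert fit.dispersion == pytest.approx(cfg.nb_dispersion, abs=0.05)

    def test_null_covariates_centered_at_zero(self):
        """When counts ignore the covariates, fitted covariate coefficients
        scatter around zero across replicates."""
        coefs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 2000
            counts = pd.DataFrame(
                {
                    "DEX1": rng.poisson(3.0, n),
                    "NC1": rng.poisson(2.0, n),
                }
            )
            cov = pd.DataFrame(
                {
                    "tcr_exp": rng.normal(2, 0.5, n),
                    "cd3_exp": rng.normal(0, 1, n),
                    "cd8_exp": rng.normal(0, 1, n),
                    "donor_id": ["D00"] * n,
                }
            )
            panel = tf.DextramerPanel(counts, ["NC1"], cov)
            fit = tf.fit_background(panel, "DEX1")
            coefs.append(fit.params["cd3_exp"])
        assert abs(np.mean(coefs)) < 0.02


class TestNormalize:
    def test_zero_observed_gives_zero_dnorm(self, spiked):
        panel, _ = spiked
        fit = tf.fit_background(panel, "DEX1")
        stain = tf.normalize_stain(fit, panel, "DEX1")
        zero = panel.counts["DEX1"].to_numpy() == 0
        assert zero.any()
        np.testing.assert_array_equal(stain.values[zero], 0.0)
        assert (stain.values >= 0).all()

    @staticmethod
    def handmade_fit(panel):
        """BackgroundFit with known coefficients: expected = 2 for every cell
        (const = log 2, all other terms zero)."""
        names = ["const", "nc_NC1", "tcr_exp", "cd3_exp", "cd8_exp"]
        params = pd.Series([np.log(2.0), 0.0, 0.0, 0.0, 0.0, 0.25], index=names + ["alpha"])
        return tf.BackgroundFit(
            dex_id="DEX1", params=params, converged=True,
            design_columns=names, donor_levels=["D00"],
        )

    def test_dnorm_closed_forms(self):
        panel = constant_covariate_panel([0, 1, 2, 4, 8])
        stain = tf.normalize_stain(self.handmade_fit(panel), panel, "DEX1")
        obs = panel.counts["DEX1"].to_numpy(dtype=float)
        np.testing.assert_allclose(stain.values, np.log(obs / 2.0 + 1.0), atol=1e-12)
        assert stain.values[0] == 0.0  # observed 0 -> log 1
        assert stain.values[2] == pytest.approx(np.log(2.0))  # observed = expected

    def test_monotone_in_observed_for_fixed_expected(self):
        rng = np.random.default_rng(4)
        panel = constant_covariate_panel(rng.poisson(4.0, 1000))
        stain = tf.normalize_stain(self.handmade_fit(panel), panel, "DEX1")
        obs = panel.counts["DEX1"].to_numpy()
        order = np.argsort(obs, kind="stable")
        assert np.all(np.diff(stain.values[order]) >= -1e-12)
        strict = np.diff(obs[order]) > 0
        assert np.all(np.diff(stain.values[order])[strict] > 0)

    def test_mismatched_fit_rejected(self, spiked):
        panel, _ = spiked
        fit = tf.fit_background(panel, "DEX1")
        with pytest.raises(ValueError):
            tf.normalize_stain(fit, panel, "DEX2")


class TestBinderCalling:
    def test_spiked_binders_separate(self, spiked):
        panel, truth = spiked
        fit = tf.fit_background(panel, "DEX1")
        stain = tf.normalize_stain(fit, panel, "DEX1")
        binders = np.zeros(panel.n_cells, dtype=bool)
        binders[truth.binder_cells["DEX1"]] = True
        assert roc_auc_score(binders, stain.values) > 0.99

    def test_spike_factor_one_is_uninformative(self):
        cfg = tf.SimConfig(n_donors=4, cells_per_donor=1500, spike_factor=1.0)
        panel, truth = tf.simulate_dextramer(cfg, seed=6)
        fit = tf.fit_background(panel, "DEX1")
        stain = tf.normalize_stain(fit, panel, "DEX1")
        b = np.zeros(panel.n_cells, dtype=bool)
        b[truth.binder_cells["DEX1"]] = True
        assert abs(roc_auc_score(b, stain.values) - 0.5) < 0.05

    def test_antimode_threshold_recovers_planted_binders(self, spiked):
        panel, truth = spiked
        fit = tf.fit_background(panel, "DEX1")
        stain = tf.normalize_stain(fit, panel, "DEX1")
        called = tf.call_binders(stain, tf.find_threshold_antimode(stain))
        binders = np.zeros(panel.n_cells, dtype=bool)
        binders[truth.binder_cells["DEX1"]] = True
        assert (called.calls == binders).mean() >= 0.99

    def test_threshold_semantics(self, spiked):
        panel, _ = spiked
        fit = tf.fit_background(panel, "DEX1")
        stain = tf.normalize_stain(fit, panel, "DEX1")
        tiny = tf.call_binders(stain, 1e-12)
        np.testing.assert_array_equal(
            tiny.calls, panel.counts["DEX1"].to_numpy() > 0
        )
        none = tf.call_binders(stain, stain.values.max() + 1.0)
        assert none.calls.sum() == 0
        with pytest.raises(ValueError):
            tf.call_binders(stain, float("nan"))


def simulate_antigen_population(rng, n_clones, beta_mem=0.3, beta_dnorm=0.2, n_donors=2):
    scores = rng.normal(size=n_clones)
    dnorm = rng.normal(2.0, 0.5, n_clones)
    donors = rng.choice([f"D{j}" for j in range(n_donors)], size=n_clones)
    eta = beta_mem * scores + beta_dnorm * (dnorm - 2.0) - 0.2
    memory = (rng.random(n_clones) < 1 / (1 + np.exp(-eta))).astype(int)
    return memory, scores, dnorm, donors


class TestAntigenAssoc:
    def test_too_few_clones_ineligible(self):
        rng = np.random.default_rng(0)
        m, s, d, don = simulate_antigen_population(rng, 9)
        res = tf.antigen_assoc(m, s, d, don)
        assert not res.eligible and not res.estimable

    def test_single_class_flagged_inestimable(self):
        rng = np.random.default_rng(1)
        _, s, d, don = simulate_antigen_population(rng, 30)
        res = tf.antigen_assoc(np.ones(30, dtype=int), s, d, don)
        assert res.eligible and not res.estimable

    def test_recovers_true_effect(self):
        # standardized errors (beta_hat - beta)/se over replicates center on 0
        zs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m, s, d, don = simulate_antigen_population(rng, 300, beta_mem=0.3)
            res = tf.antigen_assoc(m, s, d, don)
            assert res.estimable
            zs.append((res.beta - 0.3) / res.se)
        assert abs(np.mean(zs)) < 1.0  # ~2.2 sd of the mean of 5 z-scores

    def test_dnorm_covariate_negligible_when_independent(self):
        """If staining intensity is generated independently of the TCR score,
        dropping it moves the score effect by less than 2 se."""
        rng = np.random.default_rng(3)
        m, s, d, don = simulate_antigen_population(rng, 500, beta_mem=0.3, beta_dnorm=0.0)
        with_d = tf.antigen_assoc(m, s, d, don)
        without_d = tf.antigen_assoc(m, s, None, don)
        assert abs(with_d.beta - without_d.beta) < 2 * with_d.se

    def test_shuffled_scores_not_significant_usually(self):
        rng = np.random.default_rng(4)
        rejections = 0
        for _ in range(30):
            m, s, d, don = simulate_antigen_population(rng, 200, beta_mem=0.0)
            res = tf.antigen_assoc(m, rng.permutation(s), d, don)
            rejections += res.p < 0.05
        assert rejections <= 6  # ~5% expected; generous binomial bound


class TestAcrossAntigenMeta:
    def test_identical_results_pool_to_common_value(self):
        results = [
            tf.AntigenAssocResult(
                antigen=f"a{i}", n_clones=50, n_donors=2, eligible=True,
                estimable=True, beta=0.11, se=0.05, p=0.03,
            )
            for i in range(5)
        ]
        meta = tf.across_antigen_meta(results)
        assert meta.mu == pytest.approx(0.11)
        assert meta.I2 == pytest.approx(0.0)

    def test_too_few_results_rejected(self):
        one = tf.AntigenAssocResult(
            antigen="a", n_clones=50, n_donors=1, eligible=True, estimable=True,
            beta=0.1, se=0.05, p=0.04,
        )
        with pytest.raises(ValueError):
            tf.across_antigen_meta([one])

    def test_29_population_design_recovers_pooled_effect(self):
        """Mirrors the across-antigen design at synthetic scale: 29 populations
        drawn around a small common effect pool back to it."""
        rng = np.random.default_rng(5)
        results = []
        for i in range(29):
            m, s, d, don = simulate_antigen_population(
                rng, 120, beta_mem=0.11 + rng.normal(0, 0.03)
            )
            results.append(tf.antigen_assoc(m, s, d, don, antigen=f"ag{i}"))
        meta = tf.across_antigen_meta(results)
        assert meta.k >= 25  # nearly all populations estimable
        assert meta.mu == pytest.approx(0.11, abs=3 * meta.se_mu)

    def test_planted_binder_chain_yields_positive_pooled_beta(self):
        """End-to-end: spiked binder populations whose memory state depends on
        a planted score effect give a positive pooled meta-analytic beta."""
        positives = 0
        n_seeds = 6
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            cfg = tf.SimConfig(n_donors=4, cells_per_donor=1200)
            panel, truth = tf.simulate_dextramer(cfg, seed=seed)
            results = []
            for dex in panel.dextramers:
                fit = tf.fit_background(panel, dex)
                stain = tf.normalize_stain(fit, panel, dex)
                idx = np.asarray(truth.binder_cells[dex])
                scores = rng.normal(size=len(idx))
                eta = 0.5 * scores - 0.2
                memory = (rng.random(len(idx)) < 1 / (1 + np.exp(-eta))).astype(int)
                donors = panel.covariates["donor_id"].to_numpy()[idx]
                results.append(
                    tf.antigen_assoc(memory, scores, stain.values[idx], donors, antigen=dex)
                )
            meta = tf.across_antigen_meta(results)
            positives += meta.mu > 0
        assert positives == n_seeds
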