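"""Centring, VIF, mixed-model fitting, BIC selection, and the Gibbs sampler."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import otogrowth as og
from otogrowth.exceptions import DegenerateFitError, InsufficientDataError


def lmm_table(n_per_cell=6, n_sites=3, n_dates=20, sd_site=0.0, sd_date=0.0,
              sd_resid=0.05, betas=None, seed=0):
    """Small crossed-design table with known fixed effects."""
    rng = np.random.default_rng(seed)
    betas = betas or {}
    rows = []
    u_site = rng.normal(0, sd_site, n_sites)
    u_date = rng.normal(0, sd_date, n_dates)
    dates = pd.date_range("2013-07-01", periods=n_dates)
    for s in range(n_sites):
        for d in range(n_dates):
            for _ in range(n_per_cell):
                x = {c: rng.normal() for c in og.COVARIATES}
                y = 1.0 + sum(betas.get(c, 0.0) * x[c] for c in og.COVARIATES)
                y += u_site[s] + u_date[d] + rng.normal(0, sd_resid)
                rows.append(
                    {"reef_id": f"s{s}", "growth_date": dates[d], "gi_s": y, **x}
                )
    return pd.DataFrame(rows)


class TestCentre:
    def test_example_and_idempotence(self):
        df = pd.DataFrame({"temperature": [1.0, 2.0, 3.0],
                           "tide": [0.0, 0.0, 0.0],
                           "turbidity": [1.0, 1.0, 1.0],
                           "waves": [-1.0, 0.0, 1.0]})
        out, centres = og.centre_predictors(df)
        np.testing.assert_allclose(out["temperature"], [-1, 0, 1])
        assert centres["temperature"] == 2.0
        # already-centred column is unchanged with centre 0
        np.testing.assert_allclose(out["waves"], df["waves"])
        assert centres["waves"] == 0.0
        out2, centres2 = og.centre_predictors(out)
        pd.testing.assert_frame_equal(out, out2)
        assert all(abs(c) < 1e-12 for c in centres2.values())

    def test_centring_changes_only_intercept(self):
        table = lmm_table(betas={"temperature": -0.3}, seed=4)
        raw = table.copy()
        raw[og.COVARIATES] += 5.0  # uncentred
        fit_raw = og.fit_lme(raw, ["temperature"])
        centred, _ = og.centre_predictors(raw)
        fit_cen = og.fit_lme(centred, ["temperature"])
        assert fit_cen.params["temperature"] == pytest.approx(
            fit_raw.params["temperature"], rel=1e-6
        )
        assert fit_cen.params["intercept"] != pytest.approx(
            fit_raw.params["intercept"], rel=1e-3
        )


class TestVIF:
    def test_orthogonal_covariates(self):
        n = 400
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(n, 4))
        # mean-centre then orthogonalise exactly (VIF regressions include an
        # intercept, so columns must be orthogonal to the constant too)
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        df = pd.DataFrame(q, columns=og.COVARIATES)
        vif = og.vif_screen(df).set_index("candidate")["vif"]
        np.testing.assert_allclose(vif, 1.0, atol=1e-8)

    def test_known_pairwise_correlation(self):
        """Two covariates with r = 0.8 give VIF = 1/(1-0.64) ~ 2.778."""
        n = 100000
        rng = np.random.default_rng(2)
        x = rng.normal(size=n)
        y = 0.8 * x + math.sqrt(1 - 0.64) * rng.normal(size=n)
        df = pd.DataFrame({"temperature": x, "tide": y})
        vif = og.vif_screen(df, ["temperature", "tide"]).set_index("candidate")["vif"]
        assert vif["temperature"] == pytest.approx(1 / (1 - 0.64), rel=0.02)

    def test_duplicated_covariate_flagged_unbounded(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        df = pd.DataFrame({"temperature": x, "tide": x.copy(),
                           "turbidity": rng.normal(size=50),
                           "waves": rng.normal(size=50)})
        vif = og.vif_screen(df).set_index("candidate")
        assert np.isinf(vif.loc["temperature", "vif"])
        assert bool(vif.loc["temperature", "flagged"])

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(4)
        base = rng.normal(size=(300, 4))
        base[:, 1] += 0.5 * base[:, 0]
        df = pd.DataFrame(base, columns=og.COVARIATES)
        mine = og.vif_screen(df).set_index("candidate")["vif"]
        X = sm.add_constant(df.to_numpy())
        for j, c in enumerate(og.COVARIATES):
            assert mine[c] == pytest.approx(
                variance_inflation_factor(X, j + 1), rel=1e-8
            )


class TestFitLME:
    def test_degenerate_limit_matches_ols(self):
        from conftest import strip_group_structure

        table = strip_group_structure(
            lmm_table(betas={"temperature": -0.2, "waves": 0.1}, seed=7)
        )
        fit = og.fit_lme(table, og.COVARIATES)
        X = sm.add_constant(table[list(og.COVARIATES)].to_numpy())
        ols = sm.OLS(table["gi_s"].to_numpy(), X).fit()
        for j, c in enumerate(og.COVARIATES):
            assert fit.params[c] == pytest.approx(ols.params[j + 1], rel=1e-6,
                                                  abs=1e-9)
        assert fit.singular  # variance components at the zero boundary

    def test_constant_response(self):
        table = lmm_table(seed=8)
        table["gi_s"] = 2.5
        fit = og.fit_lme(table, og.COVARIATES)
        assert fit.params["intercept"] == 2.5
        assert all(fit.params[c] == 0.0 for c in og.COVARIATES)
        assert all(v == 0.0 for v in fit.vcomp.values())

    def test_row_order_invariance(self):
        table = lmm_table(sd_site=0.05, sd_date=0.05,
                          betas={"temperature": -0.2}, seed=9)
        fit1 = og.fit_lme(table, ["temperature"])
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = og.fit_lme(shuffled, ["temperature"])
        assert fit1.params["temperature"] == pytest.approx(
            fit2.params["temperature"], rel=1e-6
        )

    def test_recovers_variance_components(self):
        table = lmm_table(n_per_cell=8, n_dates=40, sd_site=0.0, sd_date=0.2,
                          sd_resid=0.05, seed=10)
        fit = og.fit_lme(table, [])
        assert fit.vcomp["date"] == pytest.approx(0.04, rel=0.5)
        assert fit.sigma2 == pytest.approx(0.0025, rel=0.2)


class TestBICSelection:
    def test_bic_formula_oracle(self):
        table = lmm_table(n_per_cell=3, n_dates=8, seed=11)
        fit = og.fit_lme(table, ["temperature"], reml=False)
        k = 2 + 2 + 1  # intercept+slope, two variance components, residual
        assert fit.bic == pytest.approx(-2 * fit.llf + k * math.log(fit.nobs))

    def test_strong_single_effect_selected(self):
        table = lmm_table(n_per_cell=6, n_dates=25, sd_site=0.02, sd_date=0.02,
                          betas={"temperature": -0.5}, seed=12)
        sel = og.select_model_bic(table)
        assert sel.best_subset == ("temperature",)
        assert len(sel.table) == 16
        assert sel.best_fit.reml

    def test_pure_noise_prefers_intercept_only(self):
        wins = 0
        for seed in range(5):
            table = lmm_table(n_per_cell=4, n_dates=15, sd_resid=0.1, seed=seed)
            sel = og.select_model_bic(table)
            wins += sel.best_subset == ()
        assert wins >= 3

    def test_empty_candidates_rejected(self):
        with pytest.raises(InsufficientDataError):
            og.select_model_bic(lmm_table(seed=1), candidates=())


class TestGibbs:
    def test_schedule_arithmetic_and_determinism(self):
        table = lmm_table(n_per_cell=2, n_dates=10, betas={"tide": 0.3}, seed=13)
        r1 = og.gibbs_regress(table, ["tide"], seed=5)
        assert r1.draws.shape == (3, 180, 3)  # (1000-100)/5 per chain
        assert r1.combined.shape[0] == 540
        r2 = og.gibbs_regress(table, ["tide"], seed=5)
        np.testing.assert_array_equal(r1.draws, r2.draws)
        r3 = og.gibbs_regress(table, ["tide"], seed=6)
        assert not np.array_equal(r1.draws, r3.draws)
        # different seeds agree within Monte-Carlo error
        mc_se = r1.summary.loc["tide", "sd"] / math.sqrt(540)
        assert abs(
            r1.summary.loc["tide", "mean"] - r3.summary.loc["tide", "mean"]
        ) < 5 * mc_se

    def test_posterior_matches_ols_oracle(self):
        table = lmm_table(n_per_cell=4, n_dates=15,
                          betas={"temperature": -0.3, "waves": 0.15}, seed=14)
        res = og.gibbs_regress(table, ["temperature", "waves"], seed=2,
                               chain_length=4000, burnin=200)
        X = sm.add_constant(table[["temperature", "waves"]].to_numpy())
        ols = sm.OLS(table["gi_s"].to_numpy(), X).fit()
        for j, name in enumerate(["intercept", "temperature", "waves"]):
            post = res.summary.loc[name]
            mc_se = post["sd"] / math.sqrt(res.combined.shape[0])
            assert abs(post["mean"] - ols.params[j]) < 4 * mc_se
        assert (res.summary["rhat"] < 1.05).all()

    def test_rank_deficiency_rejected(self):
        table = lmm_table(seed=15)
        table["tide"] = table["temperature"]
        with pytest.raises(DegenerateFitError):
            og.gibbs_regress(table, ["temperature", "tide"], seed=1)

    def test_null_coefficient_interval_contains_zero(self):
        table = lmm_table(n_per_cell=3, n_dates=12, sd_resid=0.3, seed=16)
        res = og.gibbs_regress(table, ["turbidity"], seed=3)
        assert not res.significant("turbidity")
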