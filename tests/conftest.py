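"""Shared fixtures: small synthetic worlds reused across the module tests."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import otogrowth as og


@pytest.fixture(scope="session")
def short_env_config():
    """Six weeks of environment, three reefs, modest noise."""
    return og.EnvSimConfig(
        start_date=dt.date(2013, 6, 15),
        end_date=dt.date(2013, 8, 3),
        rng_seed=101,
    )


@pytest.fixture(scope="session")
def short_env_daily(short_env_config):
    bursts = og.simulate_environment(short_env_config)
    return og.daily_summaries(bursts)


@pytest.fixture(scope="session")
def small_growth_config():
    return og.GrowthSimConfig(
        n_fish_per_reef=15,
        beta_temperature=-0.07,
        settlement_window=(dt.date(2013, 7, 1), dt.date(2013, 7, 18)),
        capture_date=dt.date(2013, 8, 1),
        rng_seed=202,
    )


@pytest.fixture(scope="session")
def small_profiles(short_env_daily, small_growth_config):
    return og.simulate_otoliths(short_env_daily, small_growth_config)


@pytest.fixture(scope="session")
def small_aligned(small_profiles, short_env_daily):
    aligned, report = og.build_chronology(small_profiles, short_env_daily)
    return aligned


@pytest.fixture(scope="session")
def small_centred(small_aligned):
    centred, _ = og.centre_predictors(small_aligned)
    return centred


def strip_group_structure(table, response="gi_s"):
    """Project all site/date group structure out of the response residuals.

    Iterated within-group demeaning of the OLS residuals converges to the
    exact double-centred residual, so a mixed model fit on the result sits
    in the genuine zero-group-variance (degenerate) limit.
    """
    import statsmodels.api as sm

    import otogrowth as og

    X = sm.add_constant(table[list(og.COVARIATES)].to_numpy())
    ols = sm.OLS(table[response].to_numpy(), X).fit()
    resid = ols.resid.copy()
    for _ in range(100):
        resid -= pd.Series(resid).groupby(table["growth_date"].values).transform(
            "mean"
        ).to_numpy()
        resid -= pd.Series(resid).groupby(table["reef_id"].values).transform(
            "mean"
        ).to_numpy()
    out = table.copy()
    out[response] = ols.fittedvalues + resid
    return out


def make_bursts(rows):
    """Assemble a burst table from (timestamp, reef, logger, turb, temp, depth, rms)."""
    return pd.DataFrame(
        rows,
        columns=[
            "timestamp",
            "reef_id",
            "logger_id",
            "turbidity_ntu",
            "temperature_c",
            "depth_m",
            "wave_rms_m",
        ],
    )
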