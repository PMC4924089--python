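"""Abiotic-drivers model: centring, VIF screening, mixed-effects fit, BIC
subset selection, and Gibbs-sampled Bayesian regression for significance.

The response is the standardised growth index GI_s; candidate fixed effects
are the four mean-centred daily covariates (turbidity, temperature, tide,
waves); site and growth date enter as crossed random intercepts.  Variance
components are estimated by REML for reporting; fixed-effect subsets are
compared by BIC computed from ML refits (REML likelihoods are not comparable
across different fixed structures).  Significance is assessed, as in the
original analysis chain, by a fixed-effects-only Bayesian linear regression
sampled by a semi-conjugate Gibbs sampler (vague Normal prior on
coefficients, inverse-gamma(c0/2, d0/2) on the residual variance) with three
chains of length 1000, burn-in 100 and thinning 5.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .chronology import COVARIATES
from .exceptions import DegenerateFitError, InsufficientDataError


def centre_predictors(
    table: pd.DataFrame, columns: Sequence[str] = tuple(COVARIATES)
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Subtract the grand mean from each covariate; return (table, centres).

    Centring is idempotent up to the returned centres: applying it to an
    already-centred table returns centres of zero and leaves values unchanged.
    """
    df = table.copy()
    centres = {}
    for c in columns:
        col = df[c].astype(float)
        if col.isna().all():
            raise InsufficientDataError(f"covariate {c!r} is entirely missing")
        centres[c] = float(col.mean())
        df[c] = col - centres[c]
    return df, centres


def vif_screen(
    table: pd.DataFrame,
    candidates: Sequence[str] = tuple(COVARIATES),
    threshold: float = 5.0,
) -> pd.DataFrame:
    """Variance inflation factors: VIF_k = 1 / (1 − R²_k).

    R²_k comes from regressing candidate k on the remaining candidates (with
    intercept).  Perfect collinearity is reported as ``inf`` and flagged.
    """
    if len(table) < len(candidates) + 1:
        raise InsufficientDataError("need at least one more row than candidates")
    rows = []
    for k in candidates:
        others = [c for c in candidates if c != k]
        if not others:
            vif = 1.0
        else:
            X = sm.add_constant(table[others].to_numpy(float))
            y = table[k].to_numpy(float)
            r2 = sm.OLS(y, X).fit().rsquared
            vif = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"candidate": k, "vif": vif, "flagged": vif > threshold})
    return pd.DataFrame(rows)


@dataclass
class LMEFit:
    """Mixed-model fit summary shaped like a fixed-effects report table."""

    fixed: tuple[str, ...]
    params: pd.Series  # includes the intercept
    bse: pd.Series
    df: float  # residual-df fallback (Satterthwaite unavailable)
    tvalues: pd.Series
    pvalues: pd.Series
    vcomp: dict[str, float]  # site/date random-intercept variances
    sigma2: float  # residual variance
    llf: float
    bic: float
    reml: bool
    converged: bool
    singular: bool
    residuals: np.ndarray
    nobs: int
    meta: dict = field(default_factory=dict)


def _design(table: pd.DataFrame, fixed: Sequence[str], response: str):
    y = table[response].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(table))] + [table[f].to_numpy(float) for f in fixed]
    )
    names = ["intercept"] + list(fixed)
    return y, X, names


def fit_lme(
    table: pd.DataFrame,
    fixed: Sequence[str] = tuple(COVARIATES),
    response: str = "gi_s",
    site_col: str = "reef_id",
    date_col: str = "growth_date",
    reml: bool = True,
) -> LMEFit:
    """Gaussian LMM: response ~ fixed effects + (1|site) + (1|date).

    Crossed random intercepts are fit through the variance-components
    formulation (one all-encompassing group).  t-tests on fixed effects use a
    residual-df approximation (n − p) since a Satterthwaite correction is not
    available in the backend; the approximation is recorded in ``meta``.
    A variance component estimated at (or under) the boundary is reported
    with ``singular=True`` and a warning, not an error.
    """
    df = table.copy()
    if not np.all(np.isfinite(df[response].to_numpy(float))):
        raise InsufficientDataError("response contains non-finite values")
    if np.ptp(df[response].to_numpy(float)) == 0:
        # constant response: every slope and variance is exactly zero
        const = float(df[response].iloc[0])
        names = ["intercept"] + list(fixed)
        zeros = pd.Series(0.0, index=names)
        params = zeros.copy()
        params["intercept"] = const
        nan = pd.Series(np.nan, index=names)
        return LMEFit(
            fixed=tuple(fixed), params=params, bse=zeros.copy(),
            df=len(df) - len(names), tvalues=nan, pvalues=nan,
            vcomp={"site": 0.0, "date": 0.0}, sigma2=0.0,
            llf=math.inf, bic=math.nan, reml=reml, converged=True,
            singular=True, residuals=np.zeros(len(df)), nobs=len(df),
            meta={"df_method": "residual", "degenerate": "constant response"},
        )
    df["_site"] = df[site_col].astype(str)
    df["_date"] = pd.to_datetime(df[date_col]).astype(str)
    df["_one"] = 1
    for g in ("_site", "_date"):
        if df[g].nunique() < 2:
            raise InsufficientDataError(f"grouping factor {g} has < 2 levels")

    rhs = " + ".join(fixed) if fixed else "1"
    vc = {"site": "0 + C(_site)", "date": "0 + C(_date)"}
    model = sm.MixedLM.from_formula(
        f"{response} ~ {rhs}", data=df, groups="_one", vc_formula=vc
    )
    # powell reliably reaches boundary (zero-variance) solutions; keep a
    # gradient-based fallback for the rare non-convergence
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(reml=reml, method="powell")
        if not result.converged:
            result = model.fit(reml=reml, method="lbfgs")
    fit_warnings = [str(w.message) for w in caught]

    fe_index = list(result.fe_params.index)
    params = result.fe_params.rename(index={"Intercept": "intercept"})
    bse = result.bse[fe_index].rename(index={"Intercept": "intercept"})
    n = len(df)
    p = len(fe_index)
    resid_df = n - p
    tvals = params / bse
    pvals = pd.Series(
        2 * stats.t.sf(np.abs(tvals.to_numpy()), resid_df), index=tvals.index
    )
    vc_names = getattr(model.exog_vc, "names", list(vc.keys()))
    vcomp = {
        str(k): float(v) for k, v in zip(vc_names, np.asarray(result.vcomp, float))
    }
    singular = bool(np.any(np.asarray(result.vcomp, float) < 1e-10))
    if singular:
        warnings.warn("random-effect variance estimated at the boundary (zero)")
    k_params = p + len(vc) + 1  # fixed + variance components + residual
    bic = -2 * result.llf + k_params * math.log(n)
    return LMEFit(
        fixed=tuple(fixed),
        params=params,
        bse=bse,
        df=resid_df,
        tvalues=tvals,
        pvalues=pvals,
        vcomp=vcomp,
        sigma2=float(result.scale),
        llf=float(result.llf),
        bic=float(bic),
        reml=reml,
        converged=bool(result.converged),
        singular=singular,
        residuals=np.asarray(result.resid),
        nobs=n,
        meta={
            "df_method": "residual",
            "backend": "statsmodels.MixedLM",
            "warnings": fit_warnings,
        },
    )


@dataclass
class ModelSelection:
    """Ranked BIC table over fixed-effect subsets plus the REML-refit winner."""

    table: pd.DataFrame  # columns: subset, k, bic (ML), converged
    best_subset: tuple[str, ...]
    best_fit: LMEFit  # REML refit of the winning subset


def select_model_bic(
    table: pd.DataFrame,
    candidates: Sequence[str] = tuple(COVARIATES),
    response: str = "gi_s",
    **fit_kwargs,
) -> ModelSelection:
    """Enumerate all fixed-effect subsets, rank by ML BIC, refit winner by REML.

    Ties in BIC are broken toward the subset with fewer parameters.
    """
    if not candidates:
        raise InsufficientDataError("candidate set is empty")
    rows = []
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            fit = fit_lme(table, fixed=subset, response=response, reml=False,
                          **fit_kwargs)
            rows.append(
                {
                    "subset": subset,
                    "k": len(subset),
                    "bic": fit.bic,
                    "converged": fit.converged,
                }
            )
    ranked = (
        pd.DataFrame(rows)
        .sort_values(["bic", "k"], kind="mergesort")
        .reset_index(drop=True)
    )
    best_subset = tuple(ranked.loc[0, "subset"])
    best_fit = fit_lme(table, fixed=best_subset, response=response, reml=True,
                       **fit_kwargs)
    return ModelSelection(table=ranked, best_subset=best_subset, best_fit=best_fit)


# ---------------------------------------------------------------------------
# Gibbs-sampled Bayesian linear regression


@dataclass
class MCMCResult:
    """Combined posterior of a multi-chain Gibbs regression run."""

    param_names: list[str]  # coefficients then "sigma2"
    draws: np.ndarray  # (chains, kept, p + 1)
    summary: pd.DataFrame  # mean, sd, ci_2.5, ci_97.5, p_opposite_sign, rhat
    settings: dict
    seeds: list[int]

    @property
    def combined(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def significant(self, name: str) -> bool:
        """95% credible interval excludes zero."""
        row = self.summary.loc[name]
        return bool(row["ci_2.5"] > 0 or row["ci_97.5"] < 0)


def _rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor."""
    m, n = chains.shape
    half = n // 2
    split = chains[:, : 2 * half].reshape(2 * m, half)
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (half - 1) / half * w + b / half
    return float(math.sqrt(var_hat / w))


def gibbs_regress(
    table: pd.DataFrame,
    fixed: Sequence[str],
    response: str = "gi_s",
    chains: int = 3,
    chain_length: int = 1000,
    burnin: int = 100,
    thin: int = 5,
    seed: Optional[int] = None,
    seeds: Optional[Sequence[int]] = None,
    c0: float = 0.001,
    d0: float = 0.001,
    prior_precision: float = 0.0,
    rhat_threshold: float = 1.1,
) -> MCMCResult:
    """Bayesian linear regression by semi-conjugate Gibbs sampling.

    Model: y = Xβ + ε, ε ~ N(0, σ²);  β ~ N(0, B0⁻¹) with prior precision
    ``prior_precision`` (0 = flat), σ² ~ InvGamma(c0/2, d0/2).  Alternates
    the exact conditional draws β | σ² and σ² | β.  Chains are combined
    after burn-in and thinning; per-parameter split-chain R̂ is reported and
    a warning is raised if mixing is poor.
    """
    y, X, names = _design(table, fixed, response)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateFitError("design matrix is rank deficient")

    if seeds is None:
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(chains)]
    seeds = list(seeds)
    if len(seeds) != chains:
        raise InsufficientDataError("need one seed per chain")

    XtX = X.T @ X
    Xty = X.T @ y
    ols_beta = np.linalg.solve(XtX, Xty)
    ols_resid = y - X @ ols_beta
    init_sigma2 = float(ols_resid @ ols_resid / max(n - p, 1))

    kept_per_chain = (chain_length - burnin) // thin
    all_draws = np.empty((chains, kept_per_chain, p + 1))
    for c, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        sigma2 = init_sigma2
        kept = 0
        for it in range(chain_length):
            prec = XtX / sigma2 + prior_precision * np.eye(p)
            cov = np.linalg.inv(prec)
            cov = (cov + cov.T) / 2.0
            mean = cov @ (Xty / sigma2)
            beta = rng.multivariate_normal(mean, cov, method="cholesky")
            resid = y - X @ beta
            shape = (c0 + n) / 2.0
            scale = (d0 + resid @ resid) / 2.0
            sigma2 = scale / rng.gamma(shape)
            if it >= burnin and (it - burnin) % thin == 0:
                all_draws[c, kept, :p] = beta
                all_draws[c, kept, p] = sigma2
                kept += 1
        assert kept == kept_per_chain

    param_names = names + ["sigma2"]
    combined = all_draws.reshape(-1, p + 1)
    rows = []
    for j, name in enumerate(param_names):
        d = combined[:, j]
        lo, hi = np.percentile(d, [2.5, 97.5])
        mean = d.mean()
        p_opp = float(np.mean(d < 0) if mean > 0 else np.mean(d > 0))
        rows.append(
            {
                "mean": mean,
                "sd": d.std(ddof=1),
                "ci_2.5": lo,
                "ci_97.5": hi,
                "p_opposite_sign": p_opp,
                "rhat": _rhat(all_draws[:, :, j]),
            }
        )
    summary = pd.DataFrame(rows, index=param_names)
    if (summary["rhat"] > rhat_threshold).any():
        bad = summary.index[summary["rhat"] > rhat_threshold].tolist()
        warnings.warn(f"poor chain mixing (R-hat > {rhat_threshold}): {bad}")
    return MCMCResult(
        param_names=param_names,
        draws=all_draws,
        summary=summary,
        settings={
            "chains": chains,
            "chain_length": chain_length,
            "burnin": burnin,
            "thin": thin,
            "kept_per_chain": kept_per_chain,
            "c0": c0,
            "d0": d0,
            "prior_precision": prior_precision,
        },
        seeds=seeds,
    )
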