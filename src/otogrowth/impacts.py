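"""Cumulative-impact analysis: quartile-bounded factorial conditions, Monte
Carlo permutation tests, Cohen's d effect sizes, and the additive /
synergistic / antagonistic classification.

For a pair of abiotic covariates (A, B), fish-day rows are binned by whether
each covariate's daily value falls below its 25th or above its 75th
percentile (rows inside either interquartile band are discarded).  The
corner predicted by the fitted model's coefficient signs to maximise growth
is the control condition; flipping one covariate at a time gives the two
individual-effect conditions; flipping both gives the combined condition.
Growth differences among conditions are tested by label-permutation;
standardised effect sizes (Cohen's d against control, positive when the
condition depresses growth) are summed over the individual conditions and
compared to the combined condition's d:

    d_combined ≈ d_A + d_B  → additive
    d_combined >  d_A + d_B → synergistic
    d_combined <  d_A + d_B → antagonistic

with a configurable tolerance on the d scale (exact equality has probability
zero in observational data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyCellError, InsufficientDataError

CONDITIONS = ["control", "individual_a", "individual_b", "combined"]


@dataclass
class ConditionDesign:
    """Quartile cut points and orientation for one covariate pair."""

    pair: tuple[str, str]
    cuts: dict[str, tuple[float, float]]  # covariate -> (25th, 75th)
    orientation: dict[str, str]  # covariate -> "low"/"high" quantile of control
    labels: dict[str, tuple[str, str]]  # condition -> (level_a, level_b)


def build_conditions(
    table: pd.DataFrame,
    pair: tuple[str, str],
    model_signs: Mapping[str, float],
    response: str = "gi_s",
    quantiles: tuple[float, float] = (0.25, 0.75),
) -> tuple[ConditionDesign, pd.DataFrame]:
    """Assign quartile-corner rows of the aligned table to the four conditions.

    ``model_signs`` gives the fitted coefficient sign for each covariate of
    the pair: a positive sign means high values predict high growth, so the
    control takes that covariate's HIGH corner; a negative sign puts the
    control at the LOW corner.

    Returns the design plus the retained rows with a ``condition`` column.
    Quantiles use linear interpolation (the common default definition).
    """
    a, b = pair
    for c in pair:
        if c not in table.columns:
            raise InsufficientDataError(f"covariate {c!r} not in table")
        if c not in model_signs:
            raise InsufficientDataError(f"no model sign provided for {c!r}")

    cuts, level = {}, {}
    for c in pair:
        lo = float(np.quantile(table[c], quantiles[0]))
        hi = float(np.quantile(table[c], quantiles[1]))
        if not lo < hi:
            raise InsufficientDataError(f"degenerate quartile cuts for {c!r}")
        cuts[c] = (lo, hi)
        lv = np.where(
            table[c] <= lo, "low", np.where(table[c] >= hi, "high", "mid")
        )
        level[c] = pd.Series(lv, index=table.index)

    orientation = {
        c: ("high" if model_signs[c] > 0 else "low") for c in pair
    }
    flip = {"low": "high", "high": "low"}
    labels = {
        "control": (orientation[a], orientation[b]),
        "individual_a": (flip[orientation[a]], orientation[b]),
        "individual_b": (orientation[a], flip[orientation[b]]),
        "combined": (flip[orientation[a]], flip[orientation[b]]),
    }

    keep = (level[a] != "mid") & (level[b] != "mid")
    out = table[keep].copy()
    la, lb = level[a][keep], level[b][keep]
    cell_of = {v: k for k, v in labels.items()}
    out["condition"] = [cell_of[(x, y)] for x, y in zip(la, lb)]
    for cond in CONDITIONS:
        if not (out["condition"] == cond).any():
            raise EmptyCellError(
                f"condition cell {cond!r} ({labels[cond]}) received no rows"
            )
    design = ConditionDesign(pair=pair, cuts=cuts, orientation=orientation,
                             labels=labels)
    return design, out


def _f_rows(mat: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """One-way F statistic per row; groups are contiguous column segments."""
    n = mat.shape[1]
    k = len(sizes)
    grand = mat.mean(axis=1)
    seg_means = np.add.reduceat(mat, starts, axis=1) / sizes
    ssb = (sizes * (seg_means - grand[:, None]) ** 2).sum(axis=1)
    seg_sq = np.add.reduceat(mat**2, starts, axis=1)
    ssw = (seg_sq - sizes * seg_means**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f = np.where(ssw <= 1e-300, np.where(ssb > 0, np.inf, 0.0), f)
    return f


def _two_group_perm_p(
    x: np.ndarray, y: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> float:
    pooled = np.concatenate([x, y])
    nx = len(x)
    obs = abs(x.mean() - y.mean())
    # vectorised label permutation: each row of idx is one shuffled pooling
    count = 0
    for start in range(0, n_resamples, 2000):
        block = min(2000, n_resamples - start)
        idx = np.argsort(rng.random((block, len(pooled))), axis=1)
        perm = pooled[idx]
        stat = np.abs(perm[:, :nx].mean(axis=1) - perm[:, nx:].mean(axis=1))
        count += int((stat >= obs - 1e-12).sum())
    return (1 + count) / (1 + n_resamples)


def permutation_test(
    groups: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    n_resamples: int = 10000,
    seed: Optional[int] = None,
) -> dict:
    """One-way Monte Carlo permutation test plus Holm-adjusted pairwise tests.

    The omnibus statistic is the one-way F statistic on the values; its null
    distribution comes from random reassignment of group labels.  p values
    use the add-one estimator (1 + #{permuted ≥ observed}) / (1 + B), so the
    smallest attainable p is 1/(1+B).
    """
    if isinstance(groups, Mapping):
        names = list(groups.keys())
        arrays = [np.asarray(groups[g], float) for g in names]
    else:
        arrays = [np.asarray(g, float) for g in groups]
        names = [f"group{i}" for i in range(len(arrays))]
    k = len(arrays)
    if k < 2 or any(len(a) < 2 for a in arrays):
        raise InsufficientDataError("need >= 2 groups with >= 2 values each")

    values = np.concatenate(arrays)
    sizes = np.array([len(a) for a in arrays])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    if np.ptp(values) == 0:
        return {
            "statistic": 0.0,
            "p_value": 1.0,
            "pairwise": pd.DataFrame(1.0, index=names, columns=names),
            "n_resamples": n_resamples,
        }

    rng = np.random.default_rng(seed)
    obs = float(_f_rows(values[None, :], starts, sizes)[0])
    # permuting the pooled values and reading fixed contiguous segments is
    # equivalent to permuting the group labels
    count = 0
    for start in range(0, n_resamples, 2000):
        block = min(2000, n_resamples - start)
        idx = np.argsort(rng.random((block, len(values))), axis=1)
        stats = _f_rows(values[idx], starts, sizes)
        count += int((stats >= obs - 1e-12).sum())
    p_omnibus = (1 + count) / (1 + n_resamples)

    raw = []
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for i, j in pairs:
        raw.append(
            _two_group_perm_p(arrays[i], arrays[j], n_resamples, rng)
        )
    # Holm adjustment is the identity for a single comparison; skip the
    # (surprisingly expensive) library call in that case
    adj = multipletests(raw, method="holm")[1] if len(raw) > 1 else raw
    pairwise = pd.DataFrame(np.nan, index=names, columns=names)
    for (i, j), p in zip(pairs, adj):
        pairwise.iloc[i, j] = pairwise.iloc[j, i] = p
    return {
        "statistic": float(obs),
        "p_value": float(p_omnibus),
        "pairwise": pairwise,
        "n_resamples": n_resamples,
    }


def cohens_d(condition: np.ndarray, control: np.ndarray) -> float:
    """Cohen's d of a condition against the control, pooled-SD standardised.

    d = (mean_control − mean_condition) / s_pooled, with s_pooled the square
    root of the df-weighted average of the two sample variances.  Positive d
    means the condition depresses growth relative to control.
    """
    x = np.asarray(condition, float)
    y = np.asarray(control, float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("both groups need n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    pooled = ((len(x) - 1) * vx + (len(y) - 1) * vy) / (len(x) + len(y) - 2)
    if pooled <= 0:
        raise DegenerateDataError("zero pooled variance: d undefined")
    return float((y.mean() - x.mean()) / np.sqrt(pooled))


class DegenerateDataError(InsufficientDataError):
    """Zero pooled variance makes Cohen's d undefined."""


def classify_interaction(
    d_individual_a: float,
    d_individual_b: float,
    d_combined: float,
    tolerance: float = 0.1,
) -> str:
    """Classify the cumulative impact from three effect sizes.

    With s = d_A + d_B: |d_combined − s| ≤ tolerance → additive;
    d_combined > s + tolerance → synergistic; otherwise antagonistic.
    """
    for v in (d_individual_a, d_individual_b, d_combined):
        if not np.isfinite(v):
            raise InsufficientDataError("effect sizes must be finite")
    s = d_individual_a + d_individual_b
    if abs(d_combined - s) <= tolerance:
        return "additive"
    return "synergistic" if d_combined > s else "antagonistic"


@dataclass
class CumulativeImpactResult:
    """Full per-pair cumulative-impact report."""

    pair: tuple[str, str]
    design: ConditionDesign
    condition_stats: pd.DataFrame  # n, mean, sd per condition
    p_omnibus: float
    pairwise_p: pd.DataFrame
    d_individual_a: float
    d_individual_b: float
    d_combined: float
    d_sum: float
    interaction_class: str
    tolerance: float
    exceeds_strongest_individual: bool = field(default=False)

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "orientation": self.design.orientation,
            "cuts": {k: list(v) for k, v in self.design.cuts.items()},
            "condition_stats": self.condition_stats.to_dict("index"),
            "p_omnibus": self.p_omnibus,
            "pairwise_p": self.pairwise_p.to_dict(),
            "d_individual_a": self.d_individual_a,
            "d_individual_b": self.d_individual_b,
            "d_combined": self.d_combined,
            "d_sum": self.d_sum,
            "interaction_class": self.interaction_class,
            "tolerance": self.tolerance,
            "exceeds_strongest_individual": self.exceeds_strongest_individual,
        }


def cumulative_impact_analysis(
    table: pd.DataFrame,
    pair: tuple[str, str],
    model_signs: Mapping[str, float],
    response: str = "gi_s",
    n_resamples: int = 10000,
    seed: Optional[int] = None,
    tolerance: float = 0.1,
) -> CumulativeImpactResult:
    """Run the full per-pair procedure on an aligned growth table.

    Besides the additive/synergistic/antagonistic call (combined d vs summed
    individual d), the report also records whether the combined condition's d
    exceeds the strongest single individual effect — the weaker "greater than
    the individual effect alone" comparison sometimes quoted for such
    analyses; both are computed, neither is harmonised into the other.
    """
    design, assigned = build_conditions(table, pair, model_signs,
                                        response=response)
    groups = {
        c: assigned.loc[assigned["condition"] == c, response].to_numpy(float)
        for c in CONDITIONS
    }
    stats_df = pd.DataFrame(
        {
            c: {
                "n": len(v),
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
            }
            for c, v in groups.items()
        }
    ).T
    perm = permutation_test(groups, n_resamples=n_resamples, seed=seed)
    d_a = cohens_d(groups["individual_a"], groups["control"])
    d_b = cohens_d(groups["individual_b"], groups["control"])
    d_c = cohens_d(groups["combined"], groups["control"])
    cls = classify_interaction(d_a, d_b, d_c, tolerance=tolerance)
    return CumulativeImpactResult(
        pair=pair,
        design=design,
        condition_stats=stats_df,
        p_omnibus=perm["p_value"],
        pairwise_p=perm["pairwise"],
        d_individual_a=d_a,
        d_individual_b=d_b,
        d_combined=d_c,
        d_sum=d_a + d_b,
        interaction_class=cls,
        tolerance=tolerance,
        exceeds_strongest_individual=bool(d_c > max(d_a, d_b)),
    )
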