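"""Otolith growth chronologies: aging, back-dating, standardisation, alignment.

A fish's sagittal otolith accretes one growth increment per day; the width of
each post-settlement increment (µm) is the raw daily growth measure GI_w.
Ages are assigned from three independent increment counts under a
10%-of-median agreement rule.  Because increment widths decline intrinsically
with age, growth is standardised within each post-settlement age group:

    GI_s = GI_w / GI_m

where GI_m is the mean increment width of all retained fish at that age, so
mean(GI_s) = 1 within every age group by construction.  Dated increments are
then joined to the reef's daily environmental summary at a configurable lag
(default one day: food assimilated on day t-1 is deposited as growth on
day t), keeping only the first 14 post-settlement days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DegenerateFitError, InsufficientDataError, PipelineError

#: covariate names used throughout the aligned table
COVARIATES = ["turbidity", "temperature", "tide", "waves"]

#: mapping from daily-summary columns to aligned-table covariate names
_DAILY_TO_COV = {
    "turbidity_mean": "turbidity",
    "temperature_mean": "temperature",
    "tidal_range": "tide",
    "wave_rms_mean": "waves",
}


@dataclass
class OtolithProfile:
    """Per-fish otolith record: morphometrics, replicate counts, increment widths."""

    fish_id: str
    reef_id: str
    capture_date: dt.date
    standard_length_mm: float
    otolith_length_um: float
    otolith_width_um: float
    increment_counts: tuple[int, int, int]
    settlement_age: int  # increments from core to the settlement mark
    post_settlement_widths: list[float] = field(default_factory=list)
    assigned_age: Optional[float] = None  # set by the aging rule; None = excluded

    @property
    def n_post_settlement(self) -> int:
        return len(self.post_settlement_widths)


def assign_age(increment_counts: Sequence[int]) -> Optional[float]:
    """Apply the replicate-count agreement rule.

    Three independent increment counts are accepted when every count lies
    within 10% of their median; the assigned age is then the mean of the
    three counts.  Otherwise the fish is excluded (returns ``None``).
    """
    counts = np.asarray(increment_counts, dtype=float)
    if counts.shape != (3,):
        raise InsufficientDataError(f"expected exactly 3 counts, got {counts.shape}")
    if np.any(counts <= 0):
        raise InsufficientDataError("increment counts must be positive")
    med = float(np.median(counts))
    if np.all(np.abs(counts - med) <= 0.10 * med):
        return float(counts.mean())
    return None


def backdate_increments(profile: OtolithProfile) -> pd.DataFrame:
    """Date each post-settlement increment by back-calculation from capture.

    With n post-settlement increments, the increment at age ``a`` (1-based)
    formed on ``capture_date - (n - a)`` days; the settlement date is
    ``capture_date - n`` days, so the age-1 increment formed the day after
    settlement and the age-n increment formed on the capture (death) date.
    """
    n = profile.n_post_settlement
    ages = np.arange(1, n + 1)
    capture = pd.Timestamp(profile.capture_date)
    dates = capture - pd.to_timedelta(n - ages, unit="D")
    return pd.DataFrame(
        {
            "fish_id": profile.fish_id,
            "reef_id": profile.reef_id,
            "age": ages,
            "growth_date": dates,
            "gi_w": np.asarray(profile.post_settlement_widths, dtype=float),
        }
    )


def settlement_date(profile: OtolithProfile) -> dt.date:
    """Settlement date implied by the back-dating rule."""
    return profile.capture_date - dt.timedelta(days=profile.n_post_settlement)


def standardise_growth(
    rows: pd.DataFrame, by: str = "pooled", width_col: str = "gi_w"
) -> pd.DataFrame:
    """Add the standardised growth index GI_s = GI_w / GI_m per age group.

    ``by='pooled'`` (default) computes GI_m over all reefs within each
    post-settlement age group; ``by='reef'`` stratifies the mean by reef.
    """
    df = rows.copy()
    group_cols = ["age"] if by == "pooled" else ["reef_id", "age"]
    df["gi_m"] = df.groupby(group_cols)[width_col].transform("mean")
    df["gi_s"] = df[width_col] / df["gi_m"]
    return df


def align_with_environment(
    dated_rows: pd.DataFrame,
    env_daily: pd.DataFrame,
    lag_days: int = 1,
    max_age: int = 14,
) -> tuple[pd.DataFrame, dict]:
    """Join dated growth rows to the daily environment at a lag, within reef.

    Keeps ages 1..``max_age``, joins each row to its own reef's daily summary
    at ``growth_date - lag_days``, and drops (with counts) rows whose
    environmental date has no summary.

    Returns
    -------
    (aligned table, bookkeeping dict) with keys ``n_input``,
    ``n_dropped_window``, ``n_dropped_missing_env``, ``n_aligned``.
    """
    n_input = len(dated_rows)
    df = dated_rows[
        (dated_rows["age"] >= 1) & (dated_rows["age"] <= max_age)
    ].copy()
    n_dropped_window = n_input - len(df)

    df["growth_date"] = pd.to_datetime(df["growth_date"])
    df["env_date"] = df["growth_date"] - pd.to_timedelta(lag_days, unit="D")

    env = env_daily.rename(columns=_DAILY_TO_COV).copy()
    env["env_date"] = pd.to_datetime(env["date"])
    env = env[["reef_id", "env_date"] + COVARIATES]

    merged = df.merge(env, on=["reef_id", "env_date"], how="left")
    has_env = merged[COVARIATES].notna().all(axis=1)
    n_missing = int((~has_env).sum())
    aligned = merged[has_env].reset_index(drop=True)

    if aligned.empty:
        missing_dates = sorted(merged.loc[~has_env, "env_date"].dt.date.unique())
        raise PipelineError(
            "align-with-environment",
            f"join produced no rows; missing environmental dates: {missing_dates[:10]}",
        )
    report = {
        "n_input": n_input,
        "n_dropped_window": n_dropped_window,
        "n_dropped_missing_env": n_missing,
        "n_aligned": len(aligned),
    }
    return aligned, report


def somatic_relationship(profiles: Iterable[OtolithProfile]) -> dict:
    """Ordinary least-squares checks that otolith growth tracks somatic growth.

    Regresses standard length on otolith length, otolith width, and
    post-settlement age, returning slope/intercept/r² plus residuals for each
    pairing.
    """
    rows = [
        (
            p.otolith_length_um,
            p.otolith_width_um,
            p.n_post_settlement,
            p.standard_length_mm,
        )
        for p in profiles
    ]
    if len(rows) < 3:
        raise InsufficientDataError("need >= 3 fish with complete morphometrics")
    arr = np.asarray(rows, dtype=float)
    sl = arr[:, 3]
    out = {}
    for name, x in [
        ("otolith_length", arr[:, 0]),
        ("otolith_width", arr[:, 1]),
        ("post_settlement_age", arr[:, 2]),
    ]:
        if np.ptp(x) == 0:
            raise DegenerateFitError(f"zero variance in predictor {name!r}")
        fit = sm.OLS(sl, sm.add_constant(x)).fit()
        out[name] = {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "r_squared": float(fit.rsquared),
            "residuals": np.asarray(fit.resid),
            "n": len(sl),
        }
    return out


def build_chronology(
    profiles: Sequence[OtolithProfile],
    env_daily: pd.DataFrame,
    lag_days: int = 1,
    max_age: int = 14,
    standardise_by: str = "pooled",
) -> tuple[pd.DataFrame, dict]:
    """Full chronology stage: age, exclude, back-date, window, standardise, align.

    Returns the aligned growth table plus a bookkeeping report with the fish
    and fish-day conservation counts.
    """
    retained, excluded = [], []
    for p in profiles:
        p.assigned_age = assign_age(p.increment_counts)
        (retained if p.assigned_age is not None else excluded).append(p)
    if not retained:
        raise PipelineError("build-chronology", "all fish excluded by the aging rule")

    dated = pd.concat([backdate_increments(p) for p in retained], ignore_index=True)
    windowed = dated[(dated["age"] >= 1) & (dated["age"] <= max_age)].copy()
    n_dropped_window = len(dated) - len(windowed)
    windowed = standardise_growth(windowed, by=standardise_by)
    aligned, align_report = align_with_environment(
        windowed, env_daily, lag_days=lag_days, max_age=max_age
    )
    report = {
        "n_fish_input": len(profiles),
        "n_fish_retained": len(retained),
        "n_fish_excluded_aging": len(excluded),
        "n_increments_input": len(dated),
        "n_dropped_window": n_dropped_window,
        "n_dropped_missing_env": align_report["n_dropped_missing_env"],
        "n_aligned_rows": align_report["n_aligned"],
    }
    return aligned, report


# ---------------------------------------------------------------------------
# CSV round-trip (widths stored as a semicolon-delimited ordered list)

OTOLITH_COLUMNS = [
    "fish_id",
    "reef_id",
    "capture_date",
    "standard_length_mm",
    "otolith_length_um",
    "otolith_width_um",
    "count1",
    "count2",
    "count3",
    "settlement_age",
    "widths",
]


def write_otolith_csv(profiles: Sequence[OtolithProfile], path) -> None:
    rows = []
    for p in profiles:
        rows.append(
            {
                "fish_id": p.fish_id,
                "reef_id": p.reef_id,
                "capture_date": p.capture_date.isoformat(),
                "standard_length_mm": p.standard_length_mm,
                "otolith_length_um": p.otolith_length_um,
                "otolith_width_um": p.otolith_width_um,
                "count1": p.increment_counts[0],
                "count2": p.increment_counts[1],
                "count3": p.increment_counts[2],
                "settlement_age": p.settlement_age,
                "widths": ";".join(f"{w:.6g}" for w in p.post_settlement_widths),
            }
        )
    pd.DataFrame(rows, columns=OTOLITH_COLUMNS).to_csv(path, index=False)


def read_otolith_csv(path) -> list[OtolithProfile]:
    df = pd.read_csv(path)
    profiles = []
    for _, r in df.iterrows():
        profiles.append(
            OtolithProfile(
                fish_id=str(r["fish_id"]),
                reef_id=str(r["reef_id"]),
                capture_date=pd.Timestamp(r["capture_date"]).date(),
                standard_length_mm=float(r["standard_length_mm"]),
                otolith_length_um=float(r["otolith_length_um"]),
                otolith_width_um=float(r["otolith_width_um"]),
                increment_counts=(
                    int(r["count1"]),
                    int(r["count2"]),
                    int(r["count3"]),
                ),
                settlement_age=int(r["settlement_age"]),
                post_settlement_widths=[
                    float(w) for w in str(r["widths"]).split(";") if w
                ],
            )
        )
    return profiles
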