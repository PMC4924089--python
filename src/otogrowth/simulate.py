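"""Synthetic sensor logs and otolith tables with known ground truth.

The generator emulates the stated world of the field deployment: four months
of 10-minute environmental records per reef (two loggers per reef, three
reefs) with a seasonal temperature decline (~20-30 °C), spring-neap tidal
cycling produced by beating semidiurnal constituents, positive autocorrelated
wave RMS in the 0-0.16 m band, and episodic turbidity peaks lasting a few
days over a low background; and per-fish increment series whose log width
declines linearly with age and responds to the lagged (default 1 day) daily
environment through known coefficients, with lognormal fish/site/date/
residual dispersion.  Every stochastic draw flows from ``rng_seed``, so a
fixed seed yields bit-identical output streams.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .chronology import COVARIATES, OtolithProfile, _DAILY_TO_COV
from .exceptions import ConfigError

BURST_MINUTES = 10
#: principal lunar (M2) and principal solar (S2) semidiurnal periods, hours;
#: their beat (~14.77 d) generates the spring-neap cycle
M2_PERIOD_H = 12.4206012
S2_PERIOD_H = 12.0


def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1 - rho**2)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    eps = rng.normal(0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return x


@dataclass
class EnvSimConfig:
    """Parameters of the environmental simulator.

    Defaults mirror the observed regimes: temperature declining from austral
    autumn into winter, mixed semidiurnal tide with a macrotidal reef, low
    turbidity background punctuated by multi-day resuspension events, and
    wave RMS of a sheltered inshore lagoon.
    """

    start_date: dt.date = dt.date(2013, 4, 2)
    end_date: dt.date = dt.date(2013, 8, 2)
    n_reefs: int = 3
    loggers_per_reef: int = 2
    temp_start: float = 28.5  # °C at start_date
    temp_end: float = 21.0  # °C at end_date
    temp_diurnal_amp: float = 0.3  # °C, half-range of the diurnal cycle
    tidal_amplitudes: tuple[float, float] = (1.0, 0.35)  # m, (M2, S2)
    reef_tide_scale: tuple[float, ...] = (1.0, 1.2, 1.55)  # per-reef multiplier
    mean_depth: float = 6.0  # m
    wave_rms_scale: float = 0.03  # m
    wave_rho: float = 0.995  # burst-to-burst AR(1) coefficient of wave state
    turbidity_baseline: float = 3.0  # NTU
    turbidity_event_rate: float = 0.07  # events / day
    turbidity_event_peak: float = 35.0  # NTU, mean event amplitude
    turbidity_event_decay: float = 0.6  # 1/day
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "temperature": 0.15,
            "turbidity": 0.8,
            "depth": 0.02,
        }
    )  # reef-level autocorrelated noise, shared by both loggers
    logger_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "temperature": 0.02,
            "turbidity": 0.3,
            "depth": 0.01,
            "waves": 0.001,
        }
    )  # independent instrument noise per logger
    noise_rho: float = 0.95
    rng_seed: int = 0

    def validate(self) -> None:
        if self.end_date <= self.start_date:
            raise ConfigError("end_date must be after start_date")
        if self.loggers_per_reef < 1:
            raise ConfigError("loggers_per_reef must be >= 1")
        for name, v in [
            ("tidal_amplitudes", min(self.tidal_amplitudes)),
            ("wave_rms_scale", self.wave_rms_scale),
            ("turbidity_baseline", self.turbidity_baseline),
            ("turbidity_event_rate", self.turbidity_event_rate),
            ("temp_diurnal_amp", self.temp_diurnal_amp),
        ]:
            if v < 0:
                raise ConfigError(f"{name} must be >= 0")


def tidal_elevation(
    t_hours: np.ndarray, amplitudes: tuple[float, float]
) -> np.ndarray:
    """Deterministic two-constituent tide: A1·cos(ω_M2 t) + A2·cos(ω_S2 t)."""
    a1, a2 = amplitudes
    return a1 * np.cos(2 * np.pi * t_hours / M2_PERIOD_H) + a2 * np.cos(
        2 * np.pi * t_hours / S2_PERIOD_H
    )


def simulate_environment(config: EnvSimConfig) -> pd.DataFrame:
    """Generate the burst table for all reefs and loggers.

    The two loggers of a reef observe the same reef-level signal (seasonal
    and diurnal temperature, tide, wave state, turbidity events, reef-level
    autocorrelated noise) plus independent instrument noise.  Turbidity and
    wave RMS are floored at zero.
    """
    config.validate()
    times = pd.date_range(
        pd.Timestamp(config.start_date),
        pd.Timestamp(config.end_date),
        freq=f"{BURST_MINUTES}min",
        inclusive="left",
    )
    n = len(times)
    if n <= 0:
        raise ConfigError("date range yields no 10-minute steps")
    t_hours = (times - times[0]) / pd.Timedelta(hours=1)
    t_hours = np.asarray(t_hours, dtype=float)
    t_days = t_hours / 24.0
    total_days = (config.end_date - config.start_date).days

    rng = np.random.default_rng(config.rng_seed)
    frames = []
    for r in range(config.n_reefs):
        reef_id = f"reef{r + 1}"
        tide_scale = (
            config.reef_tide_scale[r % len(config.reef_tide_scale)]
            if config.reef_tide_scale
            else 1.0
        )

        frac = t_days / total_days
        temp_det = (
            config.temp_start
            + (config.temp_end - config.temp_start) * frac
            + config.temp_diurnal_amp * np.sin(2 * np.pi * t_hours / 24.0)
        )
        depth_det = config.mean_depth + tide_scale * tidal_elevation(
            t_hours, config.tidal_amplitudes
        )

        # reef-level stochastic components (shared by the loggers)
        temp_noise = _ar1(n, config.noise_rho, config.noise_sd.get("temperature", 0), rng)
        turb_noise = _ar1(n, config.noise_rho, config.noise_sd.get("turbidity", 0), rng)
        depth_noise = _ar1(n, config.noise_rho, config.noise_sd.get("depth", 0), rng)

        turb = np.full(n, config.turbidity_baseline) + turb_noise
        n_events = rng.poisson(config.turbidity_event_rate * total_days)
        event_times = np.sort(rng.uniform(0, total_days, n_events))
        event_peaks = rng.exponential(config.turbidity_event_peak, n_events)
        for t0, peak in zip(event_times, event_peaks):
            onset = t_days >= t0
            turb[onset] += peak * np.exp(
                -config.turbidity_event_decay * (t_days[onset] - t0)
            )

        if config.wave_rms_scale > 0:
            wave_state = _ar1(n, config.wave_rho, 1.0, rng)
            wave = config.wave_rms_scale * np.abs(wave_state)
        else:
            wave = np.zeros(n)

        for logger in range(config.loggers_per_reef):
            ln = config.logger_noise_sd
            rec = pd.DataFrame(
                {
                    "timestamp": times,
                    "reef_id": reef_id,
                    "logger_id": f"{reef_id}_L{logger + 1}",
                    "turbidity_ntu": np.maximum(
                        0.0, turb + rng.normal(0, ln.get("turbidity", 0), n)
                        if ln.get("turbidity", 0) > 0 else turb
                    ),
                    "temperature_c": temp_det
                    + temp_noise
                    + (rng.normal(0, ln["temperature"], n) if ln.get("temperature", 0) > 0 else 0.0),
                    "depth_m": depth_det
                    + depth_noise
                    + (rng.normal(0, ln["depth"], n) if ln.get("depth", 0) > 0 else 0.0),
                    "wave_rms_m": np.maximum(
                        0.0,
                        wave + (rng.normal(0, ln["waves"], n) if ln.get("waves", 0) > 0 else 0.0),
                    ),
                }
            )
            frames.append(rec)
    return pd.concat(frames, ignore_index=True)


@dataclass
class GrowthSimConfig:
    """Ground-truth parameters of the otolith growth generator.

    ``beta_*`` act on log increment width per unit of the mean-centred daily
    covariate; ``interaction`` maps a covariate pair to an extra log-width
    term applied on days when both covariates exceed their series median
    (a simple way to state synergistic/antagonistic stress surfaces).
    Dispersion terms are standard deviations on the log-width scale, so
    widths stay positive (lognormal noise).
    """

    n_fish_per_reef: int = 30
    beta_turbidity: float = 0.0
    beta_temperature: float = 0.0
    beta_tide: float = 0.0
    beta_waves: float = 0.0
    interaction: Mapping[tuple[str, str], float] = field(default_factory=dict)
    intrinsic_width_day1: float = 6.0  # µm
    intrinsic_decay: float = 0.03  # 1/day on log width
    sd_individual: float = 0.08
    sd_site: float = 0.03
    sd_date: float = 0.04
    sd_residual: float = 0.12
    # fish settled throughout the deployment (captured at a wide range of
    # ages); a wide window keeps settlement-date variance well above the
    # 14-day age-window variance, so the age-wise standardisation absorbs
    # almost none of the environmental signal
    settlement_window: tuple[dt.date, dt.date] = (
        dt.date(2013, 4, 15),
        dt.date(2013, 7, 15),
    )
    capture_date: dt.date = dt.date(2013, 8, 1)
    lag_days: int = 1
    count_sd: float = 0.5  # replicate increment-count perturbation
    target_r2: float = 0.9  # otolith-somatic morphometric coupling
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("sd_individual", "sd_site", "sd_date", "sd_residual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.intrinsic_width_day1 <= 0:
            raise ConfigError("intrinsic_width_day1 must be positive")
        lo, hi = self.settlement_window
        if hi < lo:
            raise ConfigError("settlement_window reversed")
        if not (lo < self.capture_date):
            raise ConfigError("capture_date must follow the settlement window")


def _betas(config: GrowthSimConfig) -> dict[str, float]:
    return {
        "turbidity": config.beta_turbidity,
        "temperature": config.beta_temperature,
        "tide": config.beta_tide,
        "waves": config.beta_waves,
    }


def simulate_otoliths(
    env_daily: pd.DataFrame, config: GrowthSimConfig
) -> list[OtolithProfile]:
    """Generate per-fish otolith profiles driven by the daily environment.

    For a fish of post-settlement age n, the increment at age a (formed on
    day t = capture − (n − a)) has

        log w = log(w1) − decay·(a−1) + Σ_k β_k · x̃_k(t − lag)
                + interaction terms + u_fish + u_site + u_date + ε

    with x̃ the grand-mean-centred daily covariate of the fish's reef.
    Replicate increment counts are Normal(n, count_sd) rounded, so nearly all
    fish pass the 10%-of-median aging rule while the exclusion path is still
    exercised at scale.  Morphometrics are linearly coupled to total age with
    noise chosen to hit ``target_r2``.
    """
    config.validate()
    env = env_daily.rename(columns=_DAILY_TO_COV).copy()
    env["date"] = pd.to_datetime(env["date"]).dt.date
    centres = {c: env[c].mean() for c in COVARIATES}
    medians = {c: env[c].median() for c in COVARIATES}
    env_by_reef = {
        reef: g.set_index("date")[COVARIATES] for reef, g in env.groupby("reef_id")
    }

    rng = np.random.default_rng(config.rng_seed)
    betas = _betas(config)
    lo, hi = config.settlement_window
    window_days = (hi - lo).days

    # date random effect: one draw per calendar date, shared across reefs
    all_dates = sorted(env["date"].unique())
    u_date = dict(
        zip(all_dates, rng.normal(0, config.sd_date, len(all_dates)))
    )

    profiles: list[OtolithProfile] = []
    fish_total_ages = []
    for reef in sorted(env_by_reef):
        reef_env = env_by_reef[reef]
        u_site = rng.normal(0, config.sd_site)
        for i in range(config.n_fish_per_reef):
            settle = lo + dt.timedelta(days=int(rng.integers(0, window_days + 1)))
            n = (config.capture_date - settle).days
            u_fish = rng.normal(0, config.sd_individual)
            widths = []
            for a in range(1, n + 1):
                formed = config.capture_date - dt.timedelta(days=n - a)
                env_date = formed - dt.timedelta(days=config.lag_days)
                if env_date not in reef_env.index:
                    raise ConfigError(
                        f"environment does not cover {env_date} needed by fish "
                        f"settling {settle} on {reef} (lag {config.lag_days})"
                    )
                x = reef_env.loc[env_date]
                logw = (
                    math.log(config.intrinsic_width_day1)
                    - config.intrinsic_decay * (a - 1)
                    + sum(betas[k] * (x[k] - centres[k]) for k in COVARIATES)
                    + u_fish
                    + u_site
                    + u_date[env_date]
                    + rng.normal(0, config.sd_residual)
                )
                for (c1, c2), gamma in config.interaction.items():
                    if x[c1] > medians[c1] and x[c2] > medians[c2]:
                        logw += gamma
                widths.append(math.exp(logw))

            counts = np.rint(rng.normal(n, config.count_sd, 3)).astype(int)
            counts = np.maximum(counts, 1)
            settlement_age = max(15, int(round(rng.normal(20, 2))))
            profiles.append(
                OtolithProfile(
                    fish_id=f"{reef}_F{i + 1:03d}",
                    reef_id=reef,
                    capture_date=config.capture_date,
                    standard_length_mm=np.nan,
                    otolith_length_um=np.nan,
                    otolith_width_um=np.nan,
                    increment_counts=tuple(int(c) for c in counts),
                    settlement_age=settlement_age,
                    post_settlement_widths=widths,
                )
            )
            fish_total_ages.append(settlement_age + n)

    # morphometrics: linear in total age with noise sized from the realized
    # signal variance so the sample r² lands near target_r2
    ages = np.asarray(fish_total_ages, dtype=float)
    r2 = config.target_r2
    sl_signal = 8.0 + 0.45 * ages
    sl_noise_sd = math.sqrt(max(sl_signal.var(), 1e-12) * (1 - r2) / r2)
    sl = sl_signal + rng.normal(0, sl_noise_sd, len(ages))
    for morph_scale, morph_base, attr in [
        (45.0, 500.0, "otolith_length_um"),
        (30.0, 300.0, "otolith_width_um"),
    ]:
        signal = morph_base + morph_scale * sl
        noise_sd = math.sqrt(max(signal.var(), 1e-12) * (1 - r2) / r2)
        vals = signal + rng.normal(0, noise_sd, len(ages))
        for p, v in zip(profiles, vals):
            setattr(p, attr, float(v))
    for p, v in zip(profiles, sl):
        p.standard_length_mm = float(v)
    return profiles


def simulate_condition_groups(
    d_a: float,
    d_b: float,
    interaction_d: float = 0.0,
    n_per_group: int = 400,
    mean_control: float = 1.0,
    sd: float = 0.2,
    rng_seed: int = 0,
) -> dict[str, np.ndarray]:
    """Four factorial condition groups with effect sizes stated on the d scale.

    Group means: control = ``mean_control``; each individual-effect group is
    depressed by ``d·sd``; the combined group by ``(d_a + d_b +
    interaction_d)·sd``.  ``interaction_d = 0`` is an exactly additive
    surface; positive values are synergistic, negative antagonistic.

    The default group size (400, the scale of a pooled fish-day condition
    cell) keeps the sampling error of ``d_combined − (d_a + d_b)``
    (≈ sqrt(6/n) ≈ 0.12) comparable to the default additivity tolerance, so
    an exactly additive surface is classified additive more often than not.
    """
    rng = np.random.default_rng(rng_seed)
    means = {
        "control": mean_control,
        "individual_a": mean_control - d_a * sd,
        "individual_b": mean_control - d_b * sd,
        "combined": mean_control - (d_a + d_b + interaction_d) * sd,
    }
    return {k: rng.normal(m, sd, n_per_group) for k, m in means.items()}


def write_sensor_csv(bursts: pd.DataFrame, path) -> None:
    out = bursts.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)
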