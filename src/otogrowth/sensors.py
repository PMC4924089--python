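"""Sensor-burst processing: 10-minute logger records to per-reef daily summaries.

Each logger burst carries a turbidity reading (NTU), a temperature reading
(°C) and ten rapid seabed-pressure readings.  The burst mean of the pressure
readings, calibrated, gives water depth; the root-mean-square deviation of
the readings about that mean expresses wave action in metres (a flat sea
gives exactly zero).  Daily summaries average all bursts of both loggers of
a reef within a calendar day and take the within-day depth range as the
tidal range.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, SchemaError

#: canonical burst-table columns
BURST_COLUMNS = [
    "timestamp",
    "reef_id",
    "logger_id",
    "turbidity_ntu",
    "temperature_c",
    "depth_m",
    "wave_rms_m",
]

#: canonical daily-summary columns
DAILY_COLUMNS = [
    "reef_id",
    "date",
    "turbidity_mean",
    "temperature_mean",
    "wave_rms_mean",
    "tidal_range",
    "n_bursts",
]


def burst_wave_rms(pressure_readings: Sequence[float]) -> float:
    """Wave action for one burst: RMS deviation of pressures about the burst mean.

    Parameters
    ----------
    pressure_readings
        The rapid pressure readings of one burst, in metre-equivalents
        (typically 10 readings over 10 s).

    Returns
    -------
    float
        ``sqrt(mean((p - mean(p))**2))`` in metres; 0 for a flat sea.
    """
    p = np.asarray(pressure_readings, dtype=float)
    if p.size < 2:
        raise InsufficientDataError(
            f"wave RMS needs at least 2 pressure readings, got {p.size}"
        )
    return float(np.sqrt(np.mean((p - p.mean()) ** 2)))


def burst_depth(
    pressure_readings: Sequence[float], scale: float = 1.0, offset: float = 0.0
) -> float:
    """Water depth for one burst: affine calibration of the burst-mean pressure."""
    p = np.asarray(pressure_readings, dtype=float)
    if p.size < 1:
        raise InsufficientDataError("depth needs at least 1 pressure reading")
    return float(scale * p.mean() + offset)


def daily_summaries(
    records: pd.DataFrame, per_logger_demean: bool = False
) -> pd.DataFrame:
    """Collapse burst records to per-reef per-day environmental summaries.

    Turbidity, temperature and wave RMS are averaged over every burst of
    every logger of the reef that calendar day; tidal range is the max minus
    min of burst depth over the same bursts.  Days with no bursts are simply
    absent.  ``n_bursts`` is reported so short days can be filtered by the
    caller.

    Parameters
    ----------
    records
        Burst table with :data:`BURST_COLUMNS`.
    per_logger_demean
        If True, subtract each logger's overall mean depth before computing
        tidal range, so a fixed depth offset between the two loggers of a
        reef does not inflate the range.
    """
    df = records.copy()
    missing = [c for c in BURST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"burst table missing columns: {missing}")

    # a logger id must not span reefs
    reef_per_logger = df.groupby("logger_id")["reef_id"].nunique()
    bad = reef_per_logger[reef_per_logger > 1]
    if len(bad):
        raise SchemaError(f"logger ids appear under multiple reefs: {list(bad.index)}")

    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.date

    depth = df["depth_m"].astype(float)
    if per_logger_demean:
        depth = depth - df.groupby("logger_id")["depth_m"].transform("mean")
    df["_depth"] = depth

    grouped = df.groupby(["reef_id", "date"], sort=True)
    out = grouped.agg(
        turbidity_mean=("turbidity_ntu", "mean"),
        temperature_mean=("temperature_c", "mean"),
        wave_rms_mean=("wave_rms_m", "mean"),
        depth_max=("_depth", "max"),
        depth_min=("_depth", "min"),
        n_bursts=("timestamp", "size"),
    ).reset_index()
    out["tidal_range"] = out["depth_max"] - out["depth_min"]
    return out[DAILY_COLUMNS]


def read_sensor_csv(path) -> pd.DataFrame:
    """Read a sensor-log CSV into a burst table.

    Accepts either precomputed ``depth_m``/``wave_rms_m`` columns or raw
    pressure columns ``p1..p10``; when both are present the raw readings win
    and depth/RMS are recomputed (identity calibration).
    """
    df = pd.read_csv(path)
    pcols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    if pcols:
        pcols = sorted(pcols, key=lambda c: int(c[1:]))
        pressures = df[pcols].to_numpy(float)
        mean = pressures.mean(axis=1)
        df["depth_m"] = mean
        df["wave_rms_m"] = np.sqrt(
            ((pressures - mean[:, None]) ** 2).mean(axis=1)
        )
    missing = [c for c in BURST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sensor CSV missing columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df[BURST_COLUMNS + pcols]


def write_daily_csv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, index=False)
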