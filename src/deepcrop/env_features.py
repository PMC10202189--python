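"""Greenhouse environment cleaning and input-feature engineering.

The encoder of the crop model consumes seven input factors per hour:
three measured (temperature, relative humidity, radiation) and four
daily-resolution derived factors (day-night temperature difference DIF,
daily cumulative radiation, cumulative growing degree days, daily
vapor-pressure deficit).  Daily factors are broadcast to all 24 hourly rows
of their day.

Units follow greenhouse-horticulture convention: temperature in degC,
relative humidity in %, radiation in W m-2, daily cumulative radiation in
kJ m-2 day-1, season-cumulative radiation in MJ m-2, VPD in kPa, thermal
time in growing degree days above a 10 degC base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factors import DAILY_FEATURES, FEATURES

ENV_COLUMNS = ("temperature_c", "relative_humidity_pct", "radiation_w_m2")

#: base temperature for growing degree days, degC (sweet pepper)
DEFAULT_T_BASE = 10.0


@dataclass
class EnvSeries:
    """Cleaned hourly greenhouse environment.

    ``frame`` has a strict hourly DatetimeIndex with no gaps and columns
    ``temperature_c``, ``relative_humidity_pct``, ``radiation_w_m2``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ENV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"environment frame missing columns {missing}")
        idx = self.frame.index
        if len(idx) >= 2:
            deltas = np.diff(idx.asi8)
            if not (deltas == 3_600_000_000_000).all():
                raise ValueError("environment index is not strictly hourly")
        rh = self.frame["relative_humidity_pct"].to_numpy()
        if ((rh < 0) | (rh > 100)).any():
            raise ValueError("relative humidity outside [0, 100]")
        if (self.frame["radiation_w_m2"].to_numpy() < 0).any():
            raise ValueError("negative radiation")

    @property
    def n_hours(self) -> int:
        return len(self.frame)

    def full_days(self) -> pd.DataFrame:
        """Rows of the frame restricted to complete midnight-to-midnight days."""
        frame = self.frame
        counts = frame.groupby(frame.index.normalize()).size()
        complete = counts[counts == 24].index
        dropped = counts[counts != 24]
        if len(dropped):
            warnings.warn(
                f"dropping {len(dropped)} partial day(s): "
                f"{[str(d.date()) for d in dropped.index]}",
                stacklevel=2,
            )
        return frame[frame.index.normalize().isin(complete)]


@dataclass
class FeatureMatrix:
    """Hourly (24*L, 7) model-input window for memory length L days."""

    values: np.ndarray          # (24*L, 7), column order = FEATURES
    day_index: np.ndarray       # (24*L,) day label per row

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURES):
            raise ValueError(f"feature matrix must be (24*L, {len(FEATURES)})")
        if self.values.shape[0] % 24 != 0:
            raise ValueError("feature matrix row count must be a multiple of 24")

    @property
    def memory_length(self) -> int:
        return self.values.shape[0] // 24


def read_env_csv(path) -> pd.DataFrame:
    """Read a raw environment CSV (may contain gaps) into an hourly frame."""
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    frame = frame.set_index("timestamp").sort_index()
    missing = [c for c in ENV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"environment CSV missing columns {missing}")
    return frame[list(ENV_COLUMNS)]


def write_env_csv(env: EnvSeries, path) -> None:
    env.frame.rename_axis("timestamp").to_csv(path, float_format="%.6g")


def interpolate_missing_env(raw: pd.DataFrame) -> tuple[EnvSeries, float]:
    """Fill hourly gaps by 1-D linear interpolation per variable.

    Missing hours (absent rows or NaN cells) are filled independently per
    variable from the nearest valid neighbours.  Returns the cleaned series
    and the fraction of hour-cells that were filled.

    Raises if a variable has a leading/trailing gap (nothing to bracket it)
    or fewer than two valid records.
    """
    if raw.empty:
        raise ValueError("empty environment table")
    full_index = pd.date_range(raw.index[0], raw.index[-1], freq="h")
    frame = raw.reindex(full_index)
    n_missing = int(frame[list(ENV_COLUMNS)].isna().to_numpy().sum())
    for col in ENV_COLUMNS:
        series = frame[col]
        valid = series.notna()
        if valid.sum() < 2:
            raise ValueError(f"{col}: fewer than 2 valid records")
        if not valid.iloc[0] or not valid.iloc[-1]:
            first = series.first_valid_index()
            last = series.last_valid_index()
            raise ValueError(
                f"{col}: unbracketed gap at series edge "
                f"(valid span {first} .. {last}, index span "
                f"{full_index[0]} .. {full_index[-1]})"
            )
        frame[col] = series.interpolate(method="index")
    frame["relative_humidity_pct"] = frame["relative_humidity_pct"].clip(0.0, 100.0)
    frame["radiation_w_m2"] = frame["radiation_w_m2"].clip(lower=0.0)
    gap_fraction = n_missing / frame[list(ENV_COLUMNS)].size
    return EnvSeries(frame), gap_fraction


def compute_svp(temperature):
    """Saturation vapor pressure, kPa, from temperature in degC.

    SVP = 0.6113 * exp(5423 * (1/273.15 - 1/(273.15 + T)))
    (Clausius-Clapeyron form; 0.6113 kPa at the 0 degC reference).
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= -273.15):
        raise ValueError("temperature at or below absolute zero")
    out = 0.6113 * np.exp(5423.0 * (1.0 / 273.15 - 1.0 / (273.15 + t)))
    return out if out.ndim else float(out)


def compute_vpd(temperature, relative_humidity):
    """Vapor-pressure deficit, kPa: SVP(T) * (1 - RH/100)."""
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity outside [0, 100]")
    out = compute_svp(temperature) * (1.0 - rh / 100.0)
    return out if np.ndim(out) else float(out)


def compute_daily_gdd(hourly_temperature, t_base: float = DEFAULT_T_BASE) -> float:
    """Growing degree days of one day: max(0, mean(24 hourly T) - T_base).

    Negative values are floored at zero (standard agronomic convention;
    keeps cumulative thermal time non-decreasing).
    """
    temps = np.asarray(hourly_temperature, dtype=float)
    if temps.shape != (24,):
        raise ValueError(f"expected 24 hourly temperatures, got shape {temps.shape}")
    return float(max(0.0, temps.mean() - t_base))


@dataclass
class FeatureSettings:
    """Options for daily feature derivation."""

    t_base: float = DEFAULT_T_BASE
    #: "radiation": day = hours with radiation > 0; or (start_hour, end_hour)
    day_night_split: object = "radiation"
    #: daily VPD from daily-mean T and RH (True) or mean of hourly VPD (False)
    vpd_from_daily_means: bool = True


def compute_daily_features(
    env: EnvSeries, settings: FeatureSettings | None = None
) -> pd.DataFrame:
    """Per-day derived input factors plus season-cumulative status factors.

    Returns a frame indexed by date with columns ``dif_c``,
    ``daily_cum_radiation_kj``, ``daily_gdd``, ``cum_gdd``,
    ``daily_vpd_kpa``, ``cum_radiation_mj``.
    """
    settings = settings or FeatureSettings()
    frame = env.full_days()
    if frame.empty:
        raise ValueError("no complete days in environment series")
    days = frame.index.normalize()
    hours = frame.index.hour.to_numpy()

    temp = frame["temperature_c"].to_numpy()
    rh = frame["relative_humidity_pct"].to_numpy()
    rad = frame["radiation_w_m2"].to_numpy()
    if settings.day_night_split == "radiation":
        is_day = rad > 0.0
    else:
        start, end = settings.day_night_split
        is_day = (hours >= start) & (hours < end)

    rows = []
    for day, idx in frame.groupby(days).indices.items():
        t_d, rh_d, rad_d, day_mask = temp[idx], rh[idx], rad[idx], is_day[idx]
        # DIF: mean day-period minus mean night-period temperature; a day
        # with no day (or no night) hours contributes DIF = 0.
        if day_mask.any() and (~day_mask).any():
            dif = float(t_d[day_mask].mean() - t_d[~day_mask].mean())
        else:
            dif = 0.0
        cum_rad_kj = float(rad_d.sum() * 3600.0 / 1000.0)  # 1-h rectangle rule
        gdd = max(0.0, float(t_d.mean()) - settings.t_base)
        if settings.vpd_from_daily_means:
            vpd = compute_vpd(float(t_d.mean()), float(rh_d.mean()))
        else:
            vpd = float(np.mean(compute_vpd(t_d, rh_d)))
        rows.append((day, dif, cum_rad_kj, gdd, vpd))

    daily = pd.DataFrame(
        rows, columns=["date", "dif_c", "daily_cum_radiation_kj", "daily_gdd", "daily_vpd_kpa"]
    ).set_index("date")
    daily["cum_gdd"] = daily["daily_gdd"].cumsum()
    daily["cum_radiation_mj"] = daily["daily_cum_radiation_kj"].cumsum() / 1000.0
    return daily


def feature_tensor(
    env: EnvSeries, settings: FeatureSettings | None = None
) -> tuple[np.ndarray, pd.DatetimeIndex, pd.DataFrame]:
    """Assemble the full-cultivation feature array.

    Returns ``(values, dates, daily)`` where ``values`` has shape
    (n_days, 24, 7) in the fixed feature order, daily-resolution features
    broadcast across each day's 24 rows.
    """
    settings = settings or FeatureSettings()
    daily = compute_daily_features(env, settings)
    frame = env.full_days()
    days = frame.index.normalize()
    dates = pd.DatetimeIndex(daily.index)
    n_days = len(dates)
    values = np.empty((n_days, 24, len(FEATURES)), dtype=float)
    grouped = frame.groupby(days).indices
    for d, date in enumerate(dates):
        idx = grouped[date]
        block = frame.iloc[idx]
        values[d, :, 0] = block["temperature_c"].to_numpy()
        values[d, :, 1] = block["relative_humidity_pct"].to_numpy()
        values[d, :, 2] = block["radiation_w_m2"].to_numpy()
        for j, name in enumerate(DAILY_FEATURES, start=3):
            values[d, :, j] = daily.at[date, name]
    return values, dates, daily


def build_feature_matrix(
    env: EnvSeries,
    end_day: pd.Timestamp,
    memory_length: int,
    settings: FeatureSettings | None = None,
) -> FeatureMatrix:
    """Hourly (24*L, 7) input window for the L days ending at ``end_day``."""
    values, dates, _ = feature_tensor(env, settings)
    end_day = pd.Timestamp(end_day).normalize()
    loc = dates.get_indexer([end_day])[0]
    if loc < 0:
        raise ValueError(f"day {end_day.date()} not covered by environment series")
    start = loc - memory_length + 1
    if start < 0:
        raise ValueError(
            f"insufficient history before {end_day.date()}: first available "
            f"day is {dates[0].date()}"
        )
    window = values[start : loc + 1]  # (L, 24, 7)
    day_index = np.repeat(np.arange(start, loc + 1), 24)
    return FeatureMatrix(window.reshape(-1, len(FEATURES)), day_index)
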