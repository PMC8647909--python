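"""Weather-station quality control and derived daily variables.

Sub-daily station records (30-min cadence) are quality-controlled and
aggregated to daily summaries; gaps are filled by inverse-distance
weighting from neighbouring stations; and the daily agronomic variables
used for environmental covariates are derived: growing degree days
(Baskerville-Emin single-sine method), astronomical day length,
photothermal time, vapor pressure deficit (Tetens), FAO-56
Penman-Monteith reference evapotranspiration, and the daily water
balance.

Daily series are plain :class:`pandas.DataFrame` objects indexed by
date with columns ``tmax, tmin, tmean, precip, rh, solar, wind`` plus
one boolean flag column per QC rule (``flag_count, flag_range,
flag_persistence, flag_consistency, flag_imputed``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical daily variable names
DAILY_VARS = ["tmax", "tmin", "tmean", "precip", "rh", "solar", "wind"]
QC_FLAGS = ["count", "range", "persistence", "consistency", "imputed"]

# sub-daily variable -> daily column(s) it feeds
_SUBDAILY_VARS = ["temperature", "rh", "rainfall", "solar", "wind"]


@dataclass
class QCConfig:
    """Quality-control rules for sub-daily aggregation.

    ``ranges`` are physical plausibility bounds per sub-daily variable;
    observations outside them flag the day.  ``min_valid_fraction`` is
    the minimum fraction of the nominal cadence that must be present
    for a day to pass the record-count test.  Persistence (zero
    variability over a day) is tested for the variables in
    ``persistence_vars``; rainfall is excluded because a dry day
    legitimately has zero variance.
    """

    ranges: dict = field(
        default_factory=lambda: {
            "temperature": (-40.0, 50.0),
            "rh": (0.0, 100.0),
            "rainfall": (0.0, 300.0),
            "solar": (0.0, 1500.0),  # W/m2 instantaneous
            "wind": (0.0, 40.0),
        }
    )
    min_valid_fraction: float = 0.8
    records_per_day: int = 48
    persistence_vars: tuple = ("temperature", "rh", "wind")


def _empty_daily(dates) -> pd.DataFrame:
    df = pd.DataFrame(index=pd.Index(dates, name="date"), columns=DAILY_VARS, dtype=float)
    for f in QC_FLAGS:
        df[f"flag_{f}"] = False
    return df


def qc_aggregate_daily(records: pd.DataFrame, rules: QCConfig | None = None) -> pd.DataFrame:
    """Aggregate sub-daily records of a single site to QC'd daily values.

    Parameters
    ----------
    records
        Long-format frame with columns ``timestamp`` (datetime-like),
        ``variable`` (one of temperature, rh, rainfall, solar, wind)
        and ``value``.  Solar radiation is in W/m2 and is integrated to
        MJ m-2 day-1 using the record cadence.
    rules
        QC thresholds; defaults are physical plausibility bounds.

    A day failing a rule for a variable carries the rule's flag and the
    affected daily columns are set missing.  ``tmean`` is the mean of
    the daily minimum and maximum temperatures.
    """
    if rules is None:
        rules = QCConfig()
    if len(records) == 0:
        raise ValueError("empty sub-daily record set")
    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    rec["date"] = rec["timestamp"].dt.normalize()
    dates = sorted(rec["date"].unique())
    out = _empty_daily(dates)

    # seconds between consecutive records, for solar energy integration
    cadence_s = 86400.0 / rules.records_per_day

    # daily-only variable names pass through (already-daily input);
    # their range rules reuse the matching sub-daily variable's bounds
    passthrough_range = {"tmax": "temperature", "tmin": "temperature",
                         "tmean": "temperature", "precip": "rainfall"}

    for date, day in rec.groupby("date"):
        flags: set[str] = set()
        vals: dict[str, float] = {}
        for var, sub in day.groupby("variable"):
            v = pd.to_numeric(sub["value"], errors="coerce").to_numpy(float)
            n_valid = np.isfinite(v).sum()
            if rules.records_per_day > 1 and n_valid < rules.min_valid_fraction * rules.records_per_day:
                flags.add("count")
                continue
            if n_valid == 0:
                flags.add("count")
                continue
            v = v[np.isfinite(v)]
            lo, hi = rules.ranges.get(passthrough_range.get(var, var), (-np.inf, np.inf))
            if (v < lo).any() or (v > hi).any():
                flags.add("range")
                continue
            if var in rules.persistence_vars and len(v) > 1 and np.ptp(v) == 0.0:
                flags.add("persistence")
                continue
            if var == "temperature":
                vals["tmax"] = v.max()
                vals["tmin"] = v.min()
            elif var == "rainfall":
                vals["precip"] = v.sum()
            elif var == "rh":
                vals["rh"] = v.mean()
            elif var == "wind":
                vals["wind"] = v.mean()
            elif var == "solar":
                if rules.records_per_day == 1:
                    vals["solar"] = float(v[0])  # already MJ m-2 day-1
                else:
                    # W/m2 integrated over the day -> MJ m-2 day-1
                    vals["solar"] = v.sum() * cadence_s / 1e6
            elif var in passthrough_range or var in DAILY_VARS:
                vals[var] = float(v[0])

        if "tmax" in vals and "tmin" in vals:
            if vals["tmin"] > vals["tmax"]:
                flags.add("consistency")
                vals.pop("tmax"), vals.pop("tmin")
            else:
                vals.setdefault("tmean", (vals["tmax"] + vals["tmin"]) / 2.0)
        for k, v in vals.items():
            out.loc[date, k] = v
        for f in flags:
            out.loc[date, f"flag_{f}"] = True
    return out


def fill_gaps_idw(
    target: pd.DataFrame,
    neighbors: list[tuple[pd.DataFrame, float]],
    power: float = 2.0,
) -> pd.DataFrame:
    """Fill missing daily values by inverse-distance-weighted neighbours.

    ``neighbors`` is a list of ``(daily_series, distance_km)`` pairs.
    Weights are proportional to ``distance ** -power``.  Observed values
    are never modified; imputed days get the ``imputed`` flag.  Days with
    no neighbour coverage stay missing (logged).
    """
    out = target.copy()
    for col in DAILY_VARS:
        if col not in out.columns:
            continue
        missing = out.index[out[col].isna()]
        for date in missing:
            num = 0.0
            den = 0.0
            for series, dist in neighbors:
                if date in series.index and np.isfinite(series.at[date, col]):
                    w = float(dist) ** (-power)
                    num += w * float(series.at[date, col])
                    den += w
            if den > 0:
                out.at[date, col] = num / den
                out.at[date, "flag_imputed"] = True
            else:
                log.warning("no neighbour coverage for %s on %s", col, date)
    # re-derive tmean where it became computable
    m = out["tmean"].isna() & out["tmax"].notna() & out["tmin"].notna()
    out.loc[m, "tmean"] = (out.loc[m, "tmax"] + out.loc[m, "tmin"]) / 2.0
    return out


def daily_growing_degrees(tmin, tmax, base: float = 10.0):
    """Daily growing degrees above ``base`` by the Baskerville-Emin method.

    The day's temperature course is modelled as a single sine wave
    between ``tmin`` and ``tmax``.  If the whole curve is above the
    base the result is the mean exceedance ``(tmin + tmax)/2 - base``;
    if entirely below it is zero; when the curve crosses the base the
    positive part of the sine is integrated in closed form.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin > tmax")
    mean = (tmax + tmin) / 2.0
    w = (tmax - tmin) / 2.0
    gd = np.zeros(np.broadcast(tmin, tmax).shape)
    above = tmin >= base
    below = tmax <= base
    cross = ~above & ~below
    gd = np.where(above, mean - base, gd)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arcsin(np.clip(np.where(cross, (base - mean) / np.where(w == 0, 1, w), 0.0), -1, 1))
        gd_cross = ((mean - base) * (np.pi / 2.0 - theta) + w * np.cos(theta)) / np.pi
    gd = np.where(cross, gd_cross, gd)
    return gd if gd.shape else float(gd)


def day_length(latitude: float, day_of_year) -> float:
    """Astronomical day length in hours.

    Solar declination follows the standard Cooper formula; the sunset
    hour angle then gives ``N = 24 * omega_s / pi``.  Polar latitudes
    (|lat| >= 66.5) are not supported.
    """
    if abs(latitude) >= 66.5:
        raise ValueError("polar latitudes unsupported")
    doy = np.asarray(day_of_year, dtype=float)
    phi = np.radians(latitude)
    decl = 0.409 * np.sin(2.0 * np.pi / 365.0 * doy - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0))
    n = 24.0 / np.pi * ws
    return n if n.shape else float(n)


def photothermal_time(gdd, daylen):
    """Photothermal time: daily growing degrees times day length (hours)."""
    gdd = np.asarray(gdd, dtype=float)
    if np.any(gdd < 0):
        raise ValueError("gdd must be nonnegative")
    out = gdd * np.asarray(daylen, dtype=float)
    return out if out.shape else float(out)


def saturation_vapor_pressure(t):
    """Tetens saturation vapor pressure (kPa) at temperature t (degC)."""
    t = np.asarray(t, dtype=float)
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return out if out.shape else float(out)


def vapor_pressure_deficit(tmin, tmax, rh_mean):
    """Mean daily vapor pressure deficit (kPa).

    Saturation pressure is the mean of Tetens values at the daily
    extremes; actual pressure applies the mean relative humidity.
    """
    rh = np.asarray(rh_mean, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("rh outside [0, 100]")
    es = (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin)) / 2.0
    ea = es * rh / 100.0
    out = np.maximum(es - ea, 0.0)
    return out if out.shape else float(out)


def extraterrestrial_radiation(latitude: float, day_of_year) -> float:
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1)."""
    doy = np.asarray(day_of_year, dtype=float)
    phi = np.radians(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi / 365.0 * doy)
    decl = 0.409 * np.sin(2.0 * np.pi / 365.0 * doy - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0))
    gsc = 0.0820  # MJ m-2 min-1
    ra = 24.0 * 60.0 / np.pi * gsc * dr * (
        ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws)
    )
    return ra if ra.shape else float(ra)


def et0_fao56(
    tmin,
    tmax,
    rh_mean,
    wind2,
    solar_mj,
    latitude: float,
    elevation: float,
    day_of_year,
):
    """FAO-56 Penman-Monteith daily reference evapotranspiration (mm/day).

    Net radiation is computed from measured shortwave radiation with
    albedo 0.23 and the FAO net-longwave term; soil heat flux is taken
    as zero at the daily step; the psychrometric constant derives from
    elevation-adjusted atmospheric pressure.  Wind speed is at 2 m.
    Output is clipped at zero.
    """
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    t = (tmax + tmin) / 2.0
    es = (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin)) / 2.0
    ea = es * np.asarray(rh_mean, float) / 100.0
    delta = 4098.0 * (0.6108 * np.exp(17.27 * t / (t + 237.3))) / (t + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    rs = np.asarray(solar_mj, float)
    ra = extraterrestrial_radiation(latitude, day_of_year)
    rso = (0.75 + 2e-5 * elevation) * ra
    rns = (1.0 - 0.23) * rs
    sigma = 4.903e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.clip(np.where(rso > 0, rs / np.where(rso > 0, rso, 1.0), 0.0), 0.0, 1.0)
    rnl = (
        sigma
        * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4)
        / 2.0
        * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    rn = rns - rnl
    u2 = np.asarray(wind2, float)
    num = 0.408 * delta * rn + gamma * 900.0 / (t + 273.0) * u2 * np.maximum(es - ea, 0.0)
    den = delta + gamma * (1.0 + 0.34 * u2)
    et0 = np.maximum(num / den, 0.0)
    return et0 if et0.shape else float(et0)


def et0_series(daily: pd.DataFrame, latitude: float, elevation: float) -> pd.Series:
    """Apply :func:`et0_fao56` to a daily series (missing inputs -> NaN)."""
    doy = daily.index.dayofyear
    need = daily[["tmin", "tmax", "rh", "wind", "solar"]]
    ok = need.notna().all(axis=1)
    out = pd.Series(np.nan, index=daily.index, name="et0")
    if ok.any():
        sub = daily.loc[ok]
        out.loc[ok] = et0_fao56(
            sub["tmin"].to_numpy(),
            sub["tmax"].to_numpy(),
            sub["rh"].to_numpy(),
            sub["wind"].to_numpy(),
            sub["solar"].to_numpy(),
            latitude,
            elevation,
            doy[ok],
        )
    n_missing = int((~ok).sum())
    if n_missing:
        log.warning("ET0 undefined on %d days with missing inputs", n_missing)
    return out


def daily_water_balance(precip_plus_irrigation, et0):
    """Daily water balance: precipitation + irrigation minus reference ET."""
    out = np.asarray(precip_plus_irrigation, float) - np.asarray(et0, float)
    return out if out.shape else float(out)


def wind_to_2m(u_z, z: float) -> float:
    """Log-profile correction of wind speed measured at height z to 2 m."""
    if z == 2.0:
        return u_z
    return u_z * 4.87 / np.log(67.8 * z - 5.42)
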