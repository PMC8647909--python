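"""Growth-stage environmental covariates and the standardized W matrix.

Each hybrid x environment observation is characterized by 13 weather
covariates computed over three phenology-anchored growth stages —
vegetative (planting to one week before 50% silking), flowering (one
week before to two weeks after silking) and grain filling (the
following 65 days) — plus four soil-composition covariates and,
optionally, the site coordinates.  Windows are half-open day
intervals, so no day is double counted and the three stages tile
``[planting, silking + 79)`` exactly.

Frequencies (``FreqP5``, ``FreqMaxT30``, ``FreqMaxT35``) are reported
as fractions of window days so stages of different lengths are
comparable; thresholds are strict (> 5 mm, > 30 C, > 35 C).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import weather as wx

log = logging.getLogger(__name__)

#: 13 weather covariate stems, in registry order
WEATHER_COVARIATES = [
    "P",
    "FreqP5",
    "MeanT",
    "MinT",
    "MaxT",
    "GDD",
    "Photothermal.Time",
    "FreqMaxT30",
    "FreqMaxT35",
    "St30",
    "CumSumET0",
    "CumDailyWaterBalance",
    "Sdrad",
]
SOIL_COVARIATES = ["SandProp.SC", "Silt.Prop.SC", "ClayProp.SC", "OM.SC"]
STAGES = [("vegetative", "V"), ("flowering", "F"), ("grain_filling", "G")]
COORD_COLUMNS = ["longitude", "latitude"]

#: stage offsets in days: silking-7, silking+14, grain filling length 65
PRE_SILK_DAYS = 7
POST_SILK_DAYS = 14
GRAIN_FILL_DAYS = 65


def weather_column_names(stages=("V", "F", "G")) -> list:
    return [f"{stem}.{suf}" for stem in WEATHER_COVARIATES for suf in stages]


@dataclass(frozen=True)
class StageWindows:
    """Half-open growth-stage date windows anchored on planting and silking."""

    planting: dt.date
    silking: dt.date

    @property
    def vegetative(self):
        return (self.planting, self.silking - dt.timedelta(days=PRE_SILK_DAYS))

    @property
    def flowering(self):
        return (
            self.silking - dt.timedelta(days=PRE_SILK_DAYS),
            self.silking + dt.timedelta(days=POST_SILK_DAYS),
        )

    @property
    def grain_filling(self):
        start = self.silking + dt.timedelta(days=POST_SILK_DAYS)
        return (start, start + dt.timedelta(days=GRAIN_FILL_DAYS))

    def window(self, stage: str):
        return getattr(self, stage)


def stage_windows(planting: dt.date, silking: dt.date) -> StageWindows:
    """Build the three growth-stage windows; silking must be at least
    8 days after planting so the vegetative window is nonempty."""
    planting = pd.Timestamp(planting).date()
    silking = pd.Timestamp(silking).date()
    if (silking - planting).days < PRE_SILK_DAYS + 1:
        raise ValueError(
            f"silking {silking} too early after planting {planting}: "
            "vegetative window would be empty"
        )
    return StageWindows(planting=planting, silking=silking)


def derive_daily(daily: pd.DataFrame, latitude: float, elevation: float, base: float = 10.0) -> pd.DataFrame:
    """Add derived agronomic columns to a QC'd daily weather series.

    Adds ``gdd`` (Baskerville-Emin, base 10 C), ``daylen``,
    ``photothermal`` (gdd x day length), ``et0`` (FAO-56) and
    ``water_balance`` (precip + irrigation - et0).
    """
    out = daily.copy()
    doy = out.index.dayofyear
    ok = out[["tmin", "tmax"]].notna().all(axis=1)
    gdd = np.full(len(out), np.nan)
    gdd[ok.to_numpy()] = wx.daily_growing_degrees(
        out.loc[ok, "tmin"].to_numpy(), out.loc[ok, "tmax"].to_numpy(), base=base
    )
    out["gdd"] = gdd
    out["daylen"] = wx.day_length(latitude, doy)
    out["photothermal"] = out["gdd"] * out["daylen"]
    out["et0"] = wx.et0_series(out, latitude, elevation)
    out["water_balance"] = out["precip"] - out["et0"]
    return out


def _window_slice(daily: pd.DataFrame, start: dt.date, end: dt.date) -> pd.DataFrame:
    idx = pd.date_range(start, end - dt.timedelta(days=1), freq="D")
    missing = idx.difference(daily.index)
    if len(missing):
        raise ValueError(f"weather gap in window [{start}, {end}): missing days {list(missing.date)}")
    sub = daily.loc[idx]
    bad = sub[["tmin", "tmax", "tmean", "precip", "et0", "gdd", "photothermal", "solar"]].isna()
    if bad.any().any():
        days = sorted(set(sub.index[bad.any(axis=1)].date))
        raise ValueError(f"flagged/missing values in window [{start}, {end}): {days}")
    return sub


def stage_covariates(daily: pd.DataFrame, windows: StageWindows) -> dict:
    """Compute the 13 weather covariates for each of the three stages.

    ``daily`` must already carry the derived columns from
    :func:`derive_daily` and cover every window day unflagged.
    Returns a dict keyed by registry names (``P.V`` ... ``Sdrad.G``).
    """
    out: dict[str, float] = {}
    for stage, suffix in STAGES:
        start, end = windows.window(stage)
        sub = _window_slice(daily, start, end)
        n = len(sub)
        tmax = sub["tmax"].to_numpy()
        out[f"P.{suffix}"] = float(sub["precip"].sum())
        out[f"FreqP5.{suffix}"] = float((sub["precip"] > 5.0).sum() / n)
        out[f"MeanT.{suffix}"] = float(sub["tmean"].mean())
        out[f"MinT.{suffix}"] = float(sub["tmin"].mean())
        out[f"MaxT.{suffix}"] = float(sub["tmax"].mean())
        out[f"GDD.{suffix}"] = float(sub["gdd"].sum())
        out[f"Photothermal.Time.{suffix}"] = float(sub["photothermal"].sum())
        out[f"FreqMaxT30.{suffix}"] = float((tmax > 30.0).sum() / n)
        out[f"FreqMaxT35.{suffix}"] = float((tmax > 35.0).sum() / n)
        out[f"St30.{suffix}"] = float(tmax[tmax > 30.0].sum())
        out[f"CumSumET0.{suffix}"] = float(sub["et0"].sum())
        out[f"CumDailyWaterBalance.{suffix}"] = float(sub["water_balance"].sum())
        out[f"Sdrad.{suffix}"] = float(sub["solar"].sum())
    return out


#: per-trait mask of weather stages used as predictors
TRAIT_STAGE_MASK = {
    "grain_yield": ("V", "F", "G"),
    "plant_height": ("V", "F"),  # measured shortly after flowering
}


class ECScaler:
    """Column standardizer fit on training rows only, applied to any rows.

    Keeping the fit/transform split explicit prevents information from
    test environments leaking into the covariate scaling used during
    forward cross-validation.
    """

    def __init__(self):
        self.means_ = None
        self.sds_ = None
        self.columns_ = None

    def fit(self, W: pd.DataFrame) -> "ECScaler":
        sds = W.std(axis=0, ddof=1)
        keep = sds[sds > 1e-12].index
        dropped = [c for c in W.columns if c not in set(keep)]
        if dropped:
            log.warning("dropping zero-variance covariates: %s", dropped)
        self.columns_ = list(keep)
        self.means_ = W[keep].mean(axis=0)
        self.sds_ = sds[keep]
        return self

    def transform(self, W: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("scaler not fitted")
        return (W[self.columns_] - self.means_) / self.sds_

    def fit_transform(self, W: pd.DataFrame) -> pd.DataFrame:
        return self.fit(W).transform(W)

    def inverse_transform_column(self, name: str, values):
        return np.asarray(values) * self.sds_[name] + self.means_[name]


def assemble_W(
    stage_covs: pd.DataFrame,
    soil: pd.DataFrame,
    coords: pd.DataFrame | None = None,
    trait: str = "grain_yield",
) -> pd.DataFrame:
    """Assemble the raw (unstandardized) environmental covariate matrix.

    Parameters
    ----------
    stage_covs
        One row per hybrid x environment observation, columns the 39
        stage weather covariates.
    soil
        Aligned rows with the four soil columns.
    coords
        Optional aligned rows with ``longitude, latitude``.
    trait
        Determines which weather stages enter (grain filling is
        excluded for plant height).

    Standardization is a separate step (:class:`ECScaler`) so CV code
    can fit scaling on training rows only.
    """
    stages = TRAIT_STAGE_MASK.get(trait)
    if stages is None:
        raise KeyError(f"unknown trait {trait!r}; register a stage mask")
    cols = weather_column_names(stages)
    missing = [c for c in cols if c not in stage_covs.columns]
    if missing:
        raise ValueError(f"stage covariates missing columns: {missing}")
    parts = [stage_covs[cols]]
    missing_soil = [c for c in SOIL_COVARIATES if c not in soil.columns]
    if missing_soil:
        raise ValueError(f"soil table missing columns: {missing_soil}")
    parts.append(soil[SOIL_COVARIATES].set_axis(stage_covs.index, axis=0))
    if coords is not None:
        parts.append(coords[COORD_COLUMNS].set_axis(stage_covs.index, axis=0))
    return pd.concat(parts, axis=1)


def environment_pca(W_env: pd.DataFrame):
    """PCA of the per-environment weather covariate table.

    One row per environment, windows anchored at the environment's
    median silking date.  Columns are standardized before the
    decomposition.  Returns ``(scores, loadings, variance_fractions)``
    with a deterministic sign convention (largest-magnitude loading
    positive per component).
    """
    if len(W_env) < 3:
        raise ValueError("environment PCA needs at least 3 environments")
    X = W_env.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 1e-12
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    for j in range(len(s)):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = pd.DataFrame(
        u * s,
        index=W_env.index,
        columns=[f"PC{j + 1}" for j in range(len(s))],
    )
    loadings = pd.DataFrame(
        vt.T,
        index=W_env.columns[keep],
        columns=scores.columns,
    )
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    return scores, loadings, frac
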