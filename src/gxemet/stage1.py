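"""Per-environment phenotypic analysis: hybrid BLUEs, outlier removal,
and the replicate planting-date split.

Each environment (site x year) is analyzed independently with the
two-way model ``Y_ij = mu + G_i + R_j + e_ij`` — genotype fixed,
replicate random — yielding best linear unbiased estimates (BLUEs) per
hybrid.  The single random effect admits an exact profiled REML on the
variance ratio ``lambda = sigma2_R / sigma2_e``, optimized by bounded
scalar search to tolerance 1e-8.

Plots whose absolute studentized conditional residual exceeds 3 are
flagged as outliers and removed, and the BLUEs are refit once on the
cleaned data.  Replicates of one experiment planted seven or more days
apart are relabeled as distinct, unreplicated environments before any
model fitting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

log = logging.getLogger(__name__)

OUTLIER_THRESHOLD = 3.0
SPLIT_DAYS = 7


def split_environments(plots: pd.DataFrame) -> pd.DataFrame:
    """Relabel replicates planted >= 7 days apart as distinct environments.

    Such replicates experienced materially different weather at the
    same phenological stage and are treated as unreplicated
    environments.  Plots without a planting date are dropped with a
    warning.
    """
    out = plots.copy()
    out["planting_date"] = pd.to_datetime(out["planting_date"])
    missing = out["planting_date"].isna()
    if missing.any():
        log.warning("dropping %d plots with missing planting date", int(missing.sum()))
        out = out.loc[~missing]
    pieces = []
    for env, grp in out.groupby("environment", sort=False):
        dates = grp.groupby("replicate")["planting_date"].first()
        if len(dates) > 1 and (dates.max() - dates.min()).days >= SPLIT_DAYS:
            grp = grp.copy()
            grp["environment"] = [
                f"{env}_r{rep}" for rep in grp["replicate"]
            ]
            log.info("environment %s split by planting date into %d", env, len(dates))
        pieces.append(grp)
    return pd.concat(pieces, ignore_index=True)


def _reml_lambda(y: np.ndarray, X: np.ndarray, Z: np.ndarray, tol: float = 1e-8):
    """Profile REML over lambda = sigma2_R / sigma2_e for V = I + lambda ZZ'."""
    n, r = X.shape
    ZZt = Z @ Z.T

    def neg_restricted_ll(log_lam):
        lam = np.exp(log_lam)
        V = np.eye(n) + lam * ZZt
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        resid = y - X @ beta
        quad = resid @ Vi @ resid
        s2 = quad / (n - r)
        sign, logdetV = np.linalg.slogdet(V)
        sign2, logdetX = np.linalg.slogdet(XtViX)
        return 0.5 * ((n - r) * np.log(max(s2, 1e-300)) + logdetV + logdetX)

    res = minimize_scalar(
        neg_restricted_ll, bounds=(np.log(1e-10), np.log(1e6)), method="bounded",
        options={"xatol": tol},
    )
    lam = float(np.exp(res.x))
    # compare against the boundary lambda -> 0 (no replicate variance)
    if neg_restricted_ll(np.log(1e-12)) <= res.fun:
        lam = 0.0
    return lam


def fit_env_blues(env_plots: pd.DataFrame, trait: str = "trait"):
    """Fit the genotype-fixed / replicate-random model in one environment.

    Returns ``(blues, residuals)`` where ``blues`` has columns
    ``environment, hybrid, blue, n_plots`` and ``residuals`` aligns
    with the input rows carrying studentized conditional residuals
    (NaN and flagged for unreplicated environments).

    Unreplicated environments take the observed value as the BLUE.
    Environments with a single hybrid are rejected (singular design).
    """
    env = env_plots["environment"].iloc[0]
    hybrids = pd.unique(env_plots["hybrid"])
    if len(hybrids) < 2:
        raise ValueError(f"environment {env}: fewer than 2 hybrids (singular design)")
    reps = pd.unique(env_plots["replicate"])
    y = env_plots[trait].to_numpy(float)
    n = len(y)

    if len(reps) < 2 or n == len(hybrids):
        blues = env_plots.groupby("hybrid", sort=False)[trait].agg(["mean", "size"])
        out = pd.DataFrame(
            {
                "environment": env,
                "hybrid": blues.index,
                "blue": blues["mean"].to_numpy(),
                "n_plots": blues["size"].to_numpy(),
            }
        )
        resid = pd.DataFrame(
            {"residual": np.nan, "unreplicated": True}, index=env_plots.index
        )
        return out, resid

    hmap = {h: i for i, h in enumerate(hybrids)}
    rmap = {r: i for i, r in enumerate(reps)}
    X = np.zeros((n, len(hybrids)))
    X[np.arange(n), env_plots["hybrid"].map(hmap)] = 1.0
    Z = np.zeros((n, len(reps)))
    Z[np.arange(n), env_plots["replicate"].map(rmap)] = 1.0

    lam = _reml_lambda(y, X, Z)
    V = np.eye(n) + lam * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    e_cond = P @ y  # conditional residuals y - X beta - Z u
    s2e = float(y @ e_cond) / (n - len(hybrids))
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.maximum(s2e * np.diag(P), 1e-30))
        student = e_cond / denom

    counts = env_plots.groupby("hybrid", sort=False)[trait].size()
    blues = pd.DataFrame(
        {
            "environment": env,
            "hybrid": hybrids,
            "blue": beta,
            "n_plots": counts.loc[hybrids].to_numpy(),
        }
    )
    resid = pd.DataFrame(
        {"residual": student, "unreplicated": False}, index=env_plots.index
    )
    return blues, resid


def remove_outliers(
    plots: pd.DataFrame, residuals: pd.DataFrame, threshold: float = OUTLIER_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop plots with |studentized conditional residual| > threshold.

    Returns the cleaned plot table and the outlier log.  The pass runs
    once; callers refit BLUEs on the cleaned table.
    """
    joined = plots.join(residuals["residual"])
    bad = joined["residual"].abs() > threshold
    outlog = joined.loc[bad.fillna(False), ["environment", "hybrid", "replicate", "residual"]]
    if len(outlog):
        log.info("removed %d outlier plots (|t| > %g)", len(outlog), threshold)
    return plots.loc[~bad.fillna(False)], outlog


def stage1_pipeline(
    plots: pd.DataFrame, trait: str = "trait", threshold: float = OUTLIER_THRESHOLD
):
    """Full stage-1 analysis: split -> fit -> outlier removal -> refit.

    Returns ``(blues, outlier_log)``.  Environments that cannot be fit
    (single hybrid) are skipped with a warning.
    """
    plots = split_environments(plots)
    all_resid = []
    for env, grp in plots.groupby("environment", sort=False):
        try:
            _, resid = fit_env_blues(grp, trait=trait)
        except ValueError as exc:
            log.warning("skipping environment %s: %s", env, exc)
            continue
        all_resid.append(resid)
    if not all_resid:
        raise ValueError("no fittable environments")
    residuals = pd.concat(all_resid)
    cleaned, outlog = remove_outliers(plots.loc[residuals.index], residuals, threshold)
    blues = []
    for env, grp in cleaned.groupby("environment", sort=False):
        try:
            b, _ = fit_env_blues(grp, trait=trait)
        except ValueError as exc:
            log.warning("skipping environment %s after cleaning: %s", env, exc)
            continue
        blues.append(b)
    return pd.concat(blues, ignore_index=True), outlog
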