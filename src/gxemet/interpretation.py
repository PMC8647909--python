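"""Post-hoc interpretation of fitted tree ensembles: gain-based feature
importance and Friedman partial dependence profiles.

Gain importance is the total split gain attributed to each feature
across all boosting iterations, normalized so the shares sum to one.
Partial dependence fixes a feature (set) at grid values and averages
the model's predictions over the training distribution of the
remaining features; by default the grid is 25 quantile-spaced points,
which keeps the profile inside the observed data range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_GRID_POINTS = 25


def gain_importance(model, feature_names: list, provenance: pd.Series | None = None) -> pd.DataFrame:
    """Normalized gain importance of a fitted GBDT model.

    Supports the xgboost and lightgbm sklearn wrappers.  Returns a
    frame with ``feature, share`` (sharing sum 1) and a ``class`` tag
    from the feature provenance when supplied.
    """
    cls = type(model).__module__
    if "xgboost" in cls:
        booster = model.get_booster()
        booster.feature_names = [f"f{i}" for i in range(len(feature_names))]
        raw = booster.get_score(importance_type="total_gain")
        gains = np.array([raw.get(f"f{i}", 0.0) for i in range(len(feature_names))])
    elif "lightgbm" in cls:
        gains = np.asarray(model.booster_.feature_importance(importance_type="gain"), float)
    else:
        raise TypeError(f"unsupported model type for gain importance: {type(model)!r}")
    total = gains.sum()
    if total <= 0:
        raise ValueError("model has no splits; gain importance undefined")
    out = pd.DataFrame({"feature": feature_names, "share": gains / total})
    if provenance is not None:
        out["class"] = [provenance.get(f, "unknown") for f in feature_names]
    return out.sort_values("share", ascending=False).reset_index(drop=True)


def quantile_grid(values: np.ndarray, n_points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Strictly increasing grid at evenly spaced quantiles of the data."""
    qs = np.linspace(0.0, 1.0, n_points)
    grid = np.unique(np.quantile(np.asarray(values, float), qs))
    return grid


def partial_dependence(
    model,
    X: pd.DataFrame,
    features,
    grid: dict | None = None,
    n_points: int = DEFAULT_GRID_POINTS,
) -> pd.DataFrame:
    """Friedman partial dependence profile of one or two features.

    For each grid point the feature column(s) are overwritten across
    every reference row and predictions averaged.  Returns a long
    frame with the grid value(s) and the mean prediction.
    """
    if len(X) == 0:
        raise ValueError("empty reference data")
    if isinstance(features, str):
        features = [features]
    for f in features:
        if f not in X.columns:
            raise KeyError(f"feature {f!r} not in reference table")
    grids = {}
    for f in features:
        grids[f] = np.asarray(grid[f], float) if grid and f in grid else quantile_grid(X[f], n_points)

    base = X.to_numpy(float)
    cols = [X.columns.get_loc(f) for f in features]
    if len(features) == 1:
        g = grids[features[0]]
        # vectorized: tile the reference rows once per grid value
        rep = np.repeat(base[None, :, :], len(g), axis=0)
        rep[:, :, cols[0]] = g[:, None]
        preds = model.predict(rep.reshape(-1, base.shape[1])).reshape(len(g), -1)
        return pd.DataFrame({features[0]: g, "mean_prediction": preds.mean(axis=1)})
    if len(features) == 2:
        g1, g2 = grids[features[0]], grids[features[1]]
        rows = []
        for v1 in g1:
            rep = np.repeat(base[None, :, :], len(g2), axis=0)
            rep[:, :, cols[0]] = v1
            rep[:, :, cols[1]] = g2[:, None]
            preds = model.predict(rep.reshape(-1, base.shape[1])).reshape(len(g2), -1)
            for v2, m in zip(g2, preds.mean(axis=1)):
                rows.append({features[0]: v1, features[1]: v2, "mean_prediction": m})
        return pd.DataFrame(rows)
    raise ValueError("partial dependence supports one or two features")


def partial_dependence_overlay(
    models: dict, X_by_model: dict, feature: str, n_points: int = DEFAULT_GRID_POINTS
) -> pd.DataFrame:
    """PDPs of several fits (e.g. the CV training sets plus the full fit)
    stacked long with a ``training_set`` id, for overlay plotting."""
    frames = []
    for name, model in models.items():
        pdp = partial_dependence(model, X_by_model[name], feature, n_points=n_points)
        pdp["training_set"] = name
        frames.append(pdp)
    return pd.concat(frames, ignore_index=True)
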