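"""Machine-learning comparators: elastic net and two gradient-boosted
tree backends, with nested Bayesian hyperparameter tuning and fANOVA
hyperparameter importance.

Features are assembled from marker principal components, the
environmental covariate columns, one-hot year indicators and optional
site coordinates.  Zero-variance columns are dropped and continuous
columns standardized, with the transform fit on training rows only and
applied unchanged to test rows (nested-CV hygiene).

Hyperparameters are tuned by Gaussian-process Bayesian optimization
(expected improvement over a unit-cube encoding of the space),
minimizing the mean RMSE of a 5-fold x 2-repeat inner cross-validation
of the outer training set.  The resulting trial log feeds a
random-forest surrogate whose functional-ANOVA decomposition yields
per-hyperparameter and pairwise importance shares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

BACKENDS = ("elastic_net", "gbdt_a", "gbdt_b")  # gbdt_a: xgboost, gbdt_b: lightgbm

#: default marker-PC counts per trait (bounded by panel size at fit time)
TRAIT_N_PCS = {"grain_yield": 275, "plant_height": 350}


# ---------------------------------------------------------------------------
# feature assembly

def build_feature_table(
    pcs: pd.DataFrame,
    W: pd.DataFrame | None,
    years: pd.Series,
    coords: pd.DataFrame | None,
    include_W: bool = True,
    include_coords: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the raw per-observation feature table.

    All inputs are aligned per observation (``pcs`` already expanded
    from hybrids to observations).  Returns ``(X, provenance)`` where
    provenance tags each column as ``genomic_pc, ec, year, coordinate``.
    Standardization happens separately in :class:`FeatureScaler`.
    """
    n = len(pcs)
    parts, tags = [pcs.reset_index(drop=True)], {c: "genomic_pc" for c in pcs.columns}
    if include_W:
        if W is None:
            raise ValueError("include_W=True but no covariate matrix supplied")
        if len(W) != n:
            raise ValueError("misaligned covariate rows")
        parts.append(W.reset_index(drop=True))
        tags.update({c: "ec" for c in W.columns})
    year_dummies = pd.get_dummies(pd.Series(np.asarray(years)), prefix="year", dtype=float)
    if len(year_dummies) != n:
        raise ValueError("misaligned year labels")
    parts.append(year_dummies.reset_index(drop=True))
    tags.update({c: "year" for c in year_dummies.columns})
    if include_coords:
        if coords is None:
            raise ValueError("include_coords=True but no coordinates supplied")
        if len(coords) != n:
            raise ValueError("misaligned coordinates")
        parts.append(coords.reset_index(drop=True))
        tags.update({c: "coordinate" for c in coords.columns})
    X = pd.concat(parts, axis=1)
    return X, pd.Series(tags)


class FeatureScaler:
    """Drop near-zero-variance columns and standardize continuous ones.

    Fit on training rows only; one-hot year indicators pass through
    unscaled.  Stored means/SDs also let interpretation code map
    standardized axes back to original units.
    """

    def __init__(self, provenance: pd.Series):
        self.provenance = provenance
        self.columns_: list | None = None

    def fit(self, X: pd.DataFrame) -> "FeatureScaler":
        sds = X.std(axis=0, ddof=1)
        keep = [c for c in X.columns if sds[c] > 1e-10]
        dropped = [c for c in X.columns if c not in set(keep)]
        if dropped:
            log.info("dropping %d zero-variance features", len(dropped))
        self.columns_ = keep
        cont = [c for c in keep if self.provenance.get(c) != "year"]
        self.means_ = X[cont].mean(axis=0)
        self.sds_ = X[cont].std(axis=0, ddof=1)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("scaler not fitted")
        out = X[self.columns_].copy()
        cont = self.means_.index
        out[cont] = (out[cont] - self.means_) / self.sds_
        return out


# ---------------------------------------------------------------------------
# hyperparameter space

@dataclass(frozen=True)
class Hyperparam:
    name: str
    lo: float
    hi: float
    log: bool = False
    integer: bool = False

    def decode(self, u: float):
        lo, hi = (np.log(self.lo), np.log(self.hi)) if self.log else (self.lo, self.hi)
        v = lo + u * (hi - lo)
        if self.log:
            v = np.exp(v)
        return int(round(v)) if self.integer else float(v)

    def encode(self, v) -> float:
        lo, hi = (np.log(self.lo), np.log(self.hi)) if self.log else (self.lo, self.hi)
        x = np.log(v) if self.log else v
        return float((x - lo) / (hi - lo)) if hi > lo else 0.5


def default_space(backend: str) -> list:
    if backend == "elastic_net":
        return [
            Hyperparam("alpha", 1e-4, 10.0, log=True),
            Hyperparam("l1_ratio", 0.0, 1.0),
        ]
    if backend in ("gbdt_a", "gbdt_b"):
        return [
            Hyperparam("learning_rate", 1e-3, 0.3, log=True),
            Hyperparam("max_depth", 1, 12, integer=True),
            Hyperparam("n_estimators", 100, 2000, log=True, integer=True),
            Hyperparam("min_child_weight", 1, 40, log=True, integer=True),
            Hyperparam("colsample_bytree", 0.3, 1.0),
            Hyperparam("subsample", 0.5, 1.0),
        ]
    raise ValueError(f"unknown backend {backend!r}")


@dataclass
class TuneTrial:
    params: dict
    rmse: float
    iteration: int

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("RMSE must be nonnegative")


# ---------------------------------------------------------------------------
# model fitting

def _make_model(backend: str, params: dict, seed: int = 0):
    if backend == "elastic_net":
        return ElasticNet(
            alpha=params.get("alpha", 1.0),
            l1_ratio=params.get("l1_ratio", 0.5),
            max_iter=5000,
            random_state=seed,
        )
    if backend == "gbdt_a":
        from xgboost import XGBRegressor

        return XGBRegressor(
            learning_rate=params.get("learning_rate", 0.1),
            max_depth=params.get("max_depth", 6),
            n_estimators=params.get("n_estimators", 300),
            min_child_weight=params.get("min_child_weight", 1),
            colsample_bytree=params.get("colsample_bytree", 1.0),
            subsample=params.get("subsample", 1.0),
            tree_method="hist",
            random_state=seed,
            verbosity=0,
            n_jobs=1,
        )
    if backend == "gbdt_b":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(
            learning_rate=params.get("learning_rate", 0.1),
            max_depth=params.get("max_depth", 6),
            num_leaves=min(2 ** min(params.get("max_depth", 6), 10), 255),
            n_estimators=params.get("n_estimators", 300),
            min_child_samples=params.get("min_child_weight", 20),
            colsample_bytree=params.get("colsample_bytree", 1.0),
            subsample=params.get("subsample", 1.0),
            subsample_freq=1 if params.get("subsample", 1.0) < 1.0 else 0,
            random_state=seed,
            verbose=-1,
            n_jobs=1,
        )
    raise ValueError(f"unknown backend {backend!r}")


def fit_predict(backend: str, hyperparams: dict, X_train, y_train, X_test, seed: int = 0):
    """Fit the backend on the full training set and predict the test rows.

    Returns ``(predictions, fitted_model)``; the model handle feeds the
    interpretation module.
    """
    model = _make_model(backend, hyperparams, seed=seed)
    model.fit(np.asarray(X_train, float), np.asarray(y_train, float))
    preds = model.predict(np.asarray(X_test, float))
    return preds, model


def _inner_cv_rmse(backend, params, X, y, folds, repeats, seed):
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    errs = []
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for tr, te in kf.split(X):
            model = _make_model(backend, params, seed=seed)
            model.fit(X[tr], y[tr])
            p = model.predict(X[te])
            errs.append(np.sqrt(np.mean((p - y[te]) ** 2)))
    return float(np.mean(errs))


def _expected_improvement(mu, sd, best):
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return sd * (z * stats.norm.cdf(z) + stats.norm.pdf(z))


def tune_bayes_gp(
    backend: str,
    space: list,
    X,
    y,
    n_iter: int = 30,
    n_init: int = 10,
    inner_cv: tuple = (5, 2),
    seed: int = 0,
) -> tuple[dict, list]:
    """Gaussian-process Bayesian optimization of the backend's hyperparameters.

    An initial space-filling design of ``n_init`` points is followed by
    ``n_iter`` expected-improvement acquisitions; every assignment is
    scored by the mean inner-CV RMSE on the training data only.
    Returns the argmin assignment and the full trial log.
    """
    if not space:
        raise ValueError("empty hyperparameter space")
    rng = np.random.default_rng(seed)
    folds, repeats = inner_cv
    d = len(space)

    def decode(u):
        return {hp.name: hp.decode(float(ui)) for hp, ui in zip(space, u)}

    trials: list[TuneTrial] = []
    U: list[np.ndarray] = []
    scores: list[float] = []

    # latin-hypercube-style initial design
    init = (rng.permuted(np.arange(n_init)[:, None] + rng.uniform(size=(n_init, d)), axis=0)) / n_init
    seen = set()
    for i in range(n_init):
        u = init[i]
        params = decode(u)
        key = tuple(sorted(params.items()))
        if key in seen:
            continue
        seen.add(key)
        r = _inner_cv_rmse(backend, params, X, y, folds, repeats, seed)
        trials.append(TuneTrial(params=params, rmse=r, iteration=len(trials)))
        U.append(u)
        scores.append(r)

    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5, length_scale=np.full(d, 0.3)),
        normalize_y=True,
        alpha=1e-6,
        random_state=seed,
    )
    for it in range(n_iter):
        if len(set(np.round(scores, 12))) > 1:
            gp.fit(np.asarray(U), np.asarray(scores))
            cand = rng.uniform(size=(512, d))
            mu, sd = gp.predict(cand, return_std=True)
            u = cand[int(np.argmax(_expected_improvement(mu, sd, min(scores))))]
        else:
            u = rng.uniform(size=d)
        params = decode(u)
        key = tuple(sorted(params.items()))
        if key in seen:
            u = rng.uniform(size=d)
            params = decode(u)
            key = tuple(sorted(params.items()))
            if key in seen:  # degenerate space; nothing new to evaluate
                continue
        seen.add(key)
        r = _inner_cv_rmse(backend, params, X, y, folds, repeats, seed)
        trials.append(TuneTrial(params=params, rmse=r, iteration=len(trials)))
        U.append(u)
        scores.append(r)

    best = min(trials, key=lambda t: t.rmse)
    return dict(best.params), trials


# ---------------------------------------------------------------------------
# fANOVA hyperparameter importance

def _tree_boxes(tree, d):
    """Leaf boxes (bounds in the unit cube) and values of one sklearn tree."""
    t = tree.tree_
    boxes = []

    def rec(node, lo, hi):
        if t.children_left[node] == -1:
            boxes.append((lo.copy(), hi.copy(), float(t.value[node][0][0])))
            return
        f, thr = t.feature[node], t.threshold[node]
        hi2 = hi.copy()
        hi2[f] = min(hi[f], thr)
        rec(t.children_left[node], lo, hi2)
        lo2 = lo.copy()
        lo2[f] = max(lo[f], thr)
        rec(t.children_right[node], lo2, hi)

    rec(0, np.zeros(d), np.ones(d))
    return boxes


def _tree_fanova(boxes, d, pairs):
    """Exact fANOVA variance shares of one tree over the uniform unit cube."""
    lo = np.array([b[0] for b in boxes])
    hi = np.array([b[1] for b in boxes])
    val = np.array([b[2] for b in boxes])
    lens = hi - lo
    vol = lens.prod(axis=1)
    mean = float(vol @ val)
    total = float(vol @ (val**2)) - mean**2
    if total <= 0:
        return {}, {}, 0.0

    def segments(dim):
        cuts = np.unique(np.concatenate([[0.0, 1.0], lo[:, dim], hi[:, dim]]))
        return cuts[:-1], cuts[1:]

    mains = {}
    main_var = {}
    for j in range(d):
        s0, s1 = segments(j)
        mid = (s0 + s1) / 2.0
        # leaves x segments coverage in dim j
        cover = (lo[:, j][:, None] <= mid[None, :]) & (mid[None, :] < hi[:, j][:, None])
        other_vol = vol / lens[:, j]
        m = (cover * (other_vol * val)[:, None]).sum(axis=0)
        mains[j] = (s0, s1, m)
        main_var[j] = float(((s1 - s0) * (m - mean) ** 2).sum())

    pair_var = {}
    for j, k in pairs:
        s0j, s1j, mj = mains[j]
        s0k, s1k, mk = mains[k]
        midj = (s0j + s1j) / 2.0
        midk = (s0k + s1k) / 2.0
        cj = (lo[:, j][:, None] <= midj[None, :]) & (midj[None, :] < hi[:, j][:, None])
        ck = (lo[:, k][:, None] <= midk[None, :]) & (midk[None, :] < hi[:, k][:, None])
        ov = vol / (lens[:, j] * lens[:, k])
        m2 = np.einsum("l,lj,lk->jk", ov * val, cj, ck)
        lenj = (s1j - s0j)[:, None]
        lenk = (s1k - s0k)[None, :]
        vtot = float((lenj * lenk * (m2 - mean) ** 2).sum())
        pair_var[(j, k)] = max(vtot - main_var[j] - main_var[k], 0.0)
    return main_var, pair_var, total


def fanova_importance(trials: list, n_trees: int = 64, seed: int = 0) -> pd.DataFrame:
    """Random-forest fANOVA importance of hyperparameters from a trial log.

    The forest is fit to (assignment -> RMSE); each tree's partition of
    the unit cube is marginalized exactly to per-hyperparameter and
    pairwise variance shares.  Shares are in [0, 1] and sum to at most
    one (higher-order interactions absorb the rest).
    """
    if len(trials) < 20:
        raise ValueError("need at least 20 trials for importance estimation")
    names = sorted({k for t in trials for k in t.params})
    d = len(names)
    lo = {k: min(t.params[k] for t in trials) for k in names}
    hi = {k: max(t.params[k] for t in trials) for k in names}

    def enc(t):
        return [
            (t.params[k] - lo[k]) / (hi[k] - lo[k]) if hi[k] > lo[k] else 0.5 for k in names
        ]

    X = np.array([enc(t) for t in trials])
    y = np.array([t.rmse for t in trials])
    rows = []
    if np.ptp(y) == 0:
        log.warning("constant RMSE across trials; all importance shares zero")
        for j, nm in enumerate(names):
            rows.append({"term": nm, "share": 0.0, "kind": "main"})
        return pd.DataFrame(rows)

    rf = RandomForestRegressor(
        n_estimators=n_trees, max_depth=6, min_samples_leaf=2, random_state=seed
    )
    rf.fit(X, y)
    pairs = [(j, k) for j in range(d) for k in range(j + 1, d)]
    main_acc = np.zeros(d)
    pair_acc = {p: 0.0 for p in pairs}
    n_used = 0
    for est in rf.estimators_:
        boxes = _tree_boxes(est, d)
        mv, pv, total = _tree_fanova(boxes, d, pairs)
        if total <= 0:
            continue
        n_used += 1
        for j in range(d):
            main_acc[j] += mv.get(j, 0.0) / total
        for p in pairs:
            pair_acc[p] += pv.get(p, 0.0) / total
    if n_used == 0:
        n_used = 1
    for j, nm in enumerate(names):
        rows.append({"term": nm, "share": main_acc[j] / n_used, "kind": "main"})
    for (j, k), v in pair_acc.items():
        rows.append({"term": f"{names[j]}*{names[k]}", "share": v / n_used, "kind": "pair"})
    return pd.DataFrame(rows).sort_values("share", ascending=False).reset_index(drop=True)


def fanova_importance_mc(trials: list, n_samples: int = 4000, seed: int = 0, n_trees: int = 64) -> pd.DataFrame:
    """Sobol-sampling validation of the main-effect fANOVA shares.

    Monte-Carlo estimate of first-order Sobol indices of the same
    random-forest surrogate; used to cross-check the exact
    tree-marginalization path.
    """
    names = sorted({k for t in trials for k in t.params})
    d = len(names)
    lo = {k: min(t.params[k] for t in trials) for k in names}
    hi = {k: max(t.params[k] for t in trials) for k in names}
    X = np.array(
        [
            [(t.params[k] - lo[k]) / (hi[k] - lo[k]) if hi[k] > lo[k] else 0.5 for k in names]
            for t in trials
        ]
    )
    y = np.array([t.rmse for t in trials])
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_depth=6, min_samples_leaf=2, random_state=seed
    )
    rf.fit(X, y)
    rng = np.random.default_rng(seed)
    A = rng.uniform(size=(n_samples, d))
    B = rng.uniform(size=(n_samples, d))
    fA = rf.predict(A)
    var = fA.var()
    rows = []
    for j, nm in enumerate(names):
        # pick-freeze first-order estimator: C shares only coordinate j with A
        C = B.copy()
        C[:, j] = A[:, j]
        fC = rf.predict(C)
        vj = np.mean(fA * fC) - np.mean(fA) * np.mean(fC)
        rows.append({"term": nm, "share": max(vj / var, 0.0) if var > 0 else 0.0, "kind": "main"})
    return pd.DataFrame(rows)
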