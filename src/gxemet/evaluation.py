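"""Forward cross-validation schemes and predictive-ability metrics.

Four schemes mimic breeding-relevant prediction problems.  CV0 masks
every observation of one held-out year (or site): the tested genotypes
may still have records in other environments.  CV00 additionally
removes from training every observation of any genotype present in the
test set, emulating prediction of newly developed genotypes in new
environments.

Accuracy is the per-environment Pearson correlation between predicted
and observed values; environment-level correlations are combined by
inverse-sampling-variance weighting, with V(r_j) = (1 - r_j^2) /
(n_j - 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SCHEMES = ("CV0-Year", "CV00-Year", "CV0-Site", "CV00-Site")
MIN_ENV_N = 3
#: |r| = 1 has zero sampling variance; cap to keep weights finite
R_CAP = 0.9999


@dataclass
class CVSplit:
    """One train/test partition of observation indices."""

    scheme: str
    held_out_unit: object
    train: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        self.train = np.asarray(self.train)
        self.test = np.asarray(self.test)
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test overlap")


def make_cv0_splits(obs: pd.DataFrame, unit: str = "year") -> list:
    """One split per unit (year or site): the unit's observations are the
    test set, all others train.  Genotype overlap is allowed."""
    if unit not in ("year", "site"):
        raise ValueError("unit must be 'year' or 'site'")
    values = sorted(obs[unit].unique())
    if len(values) < 2:
        raise ValueError(f"need >= 2 {unit}s for forward CV")
    scheme = f"CV0-{unit.capitalize()}"
    splits = []
    idx = np.arange(len(obs))
    for v in values:
        test = idx[(obs[unit] == v).to_numpy()]
        train = idx[(obs[unit] != v).to_numpy()]
        splits.append(CVSplit(scheme=scheme, held_out_unit=v, train=train, test=test))
    return splits


def make_cv00_splits(obs: pd.DataFrame, unit: str = "year") -> list:
    """CV0 splits further filtered: training rows of any genotype that
    occurs in the test set are removed."""
    splits = []
    for s in make_cv0_splits(obs, unit):
        test_geno = set(obs["hybrid"].to_numpy()[s.test])
        keep = np.array([h not in test_geno for h in obs["hybrid"].to_numpy()[s.train]])
        train = s.train[keep]
        if len(train) == 0:
            raise ValueError(f"CV00 training set empty for held-out {unit} {s.held_out_unit}")
        splits.append(
            CVSplit(
                scheme=s.scheme.replace("CV0", "CV00"),
                held_out_unit=s.held_out_unit,
                train=train,
                test=s.test,
            )
        )
    return splits


@dataclass
class EnvCorrelation:
    environment: object
    r: float
    n: int

    @property
    def sampling_variance(self) -> float:
        r = min(abs(self.r), R_CAP)
        return (1.0 - r * r) / (self.n - 2)


def env_correlations(pred, observed, env_labels, min_n: int = MIN_ENV_N) -> list:
    """Per-environment Pearson correlation of predictions and observations.

    Environments with fewer than ``min_n`` observations or with
    zero-variance predictions/observations are skipped with a warning.
    """
    df = pd.DataFrame({"pred": np.asarray(pred, float), "obs": np.asarray(observed, float), "env": np.asarray(env_labels)})
    out = []
    for env, grp in df.groupby("env", sort=True):
        if len(grp) < min_n:
            log.warning("environment %s skipped: n=%d < %d", env, len(grp), min_n)
            continue
        if grp["pred"].std() == 0 or grp["obs"].std() == 0:
            log.warning("environment %s skipped: zero-variance vector", env)
            continue
        r = float(stats.pearsonr(grp["pred"], grp["obs"])[0])
        out.append(EnvCorrelation(environment=env, r=r, n=len(grp)))
    return out


def weighted_predictive_ability(envs: list) -> float:
    """Inverse-sampling-variance weighted mean of per-environment r.

    r_w = sum_j r_j / V(r_j) / sum_j 1 / V(r_j); correlations of
    magnitude 1 are capped at 0.9999 (their variance would be zero).
    """
    if not envs:
        raise ValueError("no environment correlations")
    num = 0.0
    den = 0.0
    for e in envs:
        if abs(e.r) >= 1.0:
            log.warning("environment %s has |r|=1; capped at %g", e.environment, R_CAP)
        v = e.sampling_variance
        num += e.r / v
        den += 1.0 / v
    return num / den


def correlation_table(envs: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"environment": e.environment, "r": e.r, "n": e.n, "V": e.sampling_variance}
            for e in envs
        ]
    )
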