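"""Model specifications and observation-level covariance kernels.

A model spec such as ``"G+E+W+GxW+GxE"`` names main effects drawn from
{G, E, S, Y, W} and interactions from {GxE, GxS, GxY, GxW}.  Each term
maps to an observation-level covariance kernel:

- G  -> Z_g G Z_g' (genomic relationship expanded to observations)
- E/S/Y -> Z Z' (block indicator: 1 when two observations share the
  factor level)
- W  -> Omega = W W' / q over the standardized environmental covariates
- interactions -> Hadamard products of the expanded kernels (Schur's
  product theorem keeps them PSD)

Dividing W W' by the number of covariate columns puts the diagonal of
Omega on the same ~1 scale as G's, so variance components are
comparable across kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GRM

MAIN_EFFECTS = ("G", "E", "S", "Y", "W")
INTERACTIONS = ("GxE", "GxS", "GxY", "GxW")


@dataclass(frozen=True)
class ModelSpec:
    """Parsed model formula over main effects and kernel interactions."""

    main_effects: tuple
    interactions: tuple

    def __post_init__(self):
        for m in self.main_effects:
            if m not in MAIN_EFFECTS:
                raise ValueError(f"unknown main effect {m!r}")
        for it in self.interactions:
            if it not in INTERACTIONS:
                raise ValueError(f"unknown interaction {it!r}")
            a, b = it.split("x")
            if a not in self.main_effects or b not in self.main_effects:
                raise ValueError(f"interaction {it} requires main effects {a} and {b}")

    @property
    def label(self) -> str:
        return "+".join(list(self.main_effects) + list(self.interactions))

    @classmethod
    def parse(cls, label: str) -> "ModelSpec":
        mains, inters = [], []
        for tok in label.replace(" ", "").split("+"):
            if not tok:
                continue
            if "x" in tok:
                inters.append(tok)
            else:
                mains.append(tok)
        return cls(main_effects=tuple(mains), interactions=tuple(inters))


@dataclass
class KernelSet:
    """Named observation-level covariance matrices for one model."""

    kernels: dict  # name -> (n_obs, n_obs) ndarray
    n_obs: int = 0

    def __post_init__(self):
        for name, K in self.kernels.items():
            K = np.asarray(K, float)
            if K.shape[0] != K.shape[1]:
                raise ValueError(f"kernel {name} not square")
            self.kernels[name] = K
            self.n_obs = K.shape[0]

    def names(self):
        return list(self.kernels)

    def __getitem__(self, name):
        return self.kernels[name]

    def items(self):
        return self.kernels.items()


def check_psd(K: np.ndarray, tol: float = 1e-6) -> float:
    """Smallest eigenvalue; raise if more negative than -tol."""
    lam_min = float(np.linalg.eigvalsh(K).min())
    if lam_min < -tol:
        raise ValueError(f"kernel not PSD: min eigenvalue {lam_min:.3e}")
    return lam_min


def _indicator_kernel(labels) -> np.ndarray:
    codes = pd.factorize(pd.Series(labels))[0]
    return (codes[:, None] == codes[None, :]).astype(float)


def build_kernels(
    spec: ModelSpec,
    grm: GRM | None,
    W: pd.DataFrame | None,
    factors: pd.DataFrame,
) -> KernelSet:
    """Expand the model spec into observation-level kernels.

    ``factors`` has one row per observation with columns among
    ``hybrid, environment, site, year``; ``W`` (if the spec uses it)
    holds the standardized covariate rows aligned with observations.
    """
    n = len(factors)
    expanded: dict[str, np.ndarray] = {}
    if "G" in spec.main_effects:
        if grm is None:
            raise ValueError("spec includes G but no GRM supplied")
        gidx = {s: i for i, s in enumerate(grm.sample_ids)}
        rows = factors["hybrid"].map(gidx)
        if rows.isna().any():
            missing = factors.loc[rows.isna(), "hybrid"].unique()
            raise KeyError(f"hybrids absent from GRM: {list(missing)[:5]}")
        ix = rows.to_numpy(int)
        expanded["G"] = grm.matrix[np.ix_(ix, ix)]
    for name, col in (("E", "environment"), ("S", "site"), ("Y", "year")):
        if name in spec.main_effects:
            expanded[name] = _indicator_kernel(factors[col])
    if "W" in spec.main_effects:
        if W is None:
            raise ValueError("spec includes W but no covariate matrix supplied")
        Wm = W.to_numpy(float)
        if Wm.shape[0] != n:
            raise ValueError("W rows not aligned with observations")
        expanded["W"] = Wm @ Wm.T / Wm.shape[1]

    kernels = {k: expanded[k] for k in spec.main_effects}
    for it in spec.interactions:
        a, b = it.split("x")
        # GxW pairs the genomic kernel with Omega
        kernels[it] = expanded[a] * expanded[b]
    return KernelSet(kernels=kernels)
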