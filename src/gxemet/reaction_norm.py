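"""Bayesian multi-kernel regression (reaction-norm models) via Gibbs
sampling, with a closed-form BLUP oracle.

The model is ``y = mu 1 + sum_k u_k + e`` with ``u_k ~ N(0, sigma2_k
K_k)`` and ``e ~ N(0, sigma2_e I)``.  Each kernel is reparameterized
through its eigendecomposition ``K_k = Phi_k Lambda_k Phi_k'``; the
orthonormality of ``Phi_k`` makes the conditional posterior of the
eigen-coefficients diagonal, so one Gibbs update per kernel costs two
matrix-vector products.  Variance components get conjugate
scaled-inverse-chi-square updates; missing responses are sampled by
data augmentation, and their posterior-mean signal is the prediction.

Priors are scaled-inverse-chi-square with 5 degrees of freedom, scales
chosen so the prior modes split half the phenotypic variance equally
among the kernels and assign the other half to the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import KernelSet, ModelSpec

log = logging.getLogger(__name__)

PRIOR_DF = 5.0
#: eigenvalues in (-PSD_TOL, 0) are clipped to 0; more negative is an error
PSD_TOL = 1e-6


@dataclass
class PosteriorSummary:
    """Posterior means/SDs and predictions from one Gibbs run."""

    mu_hat: float
    components: pd.DataFrame  # index kernel name + 'residual'; cols mean, sd, ess
    fitted: np.ndarray  # posterior mean of mu + sum_k u_k per observation
    predictions: pd.Series  # posterior-mean signal for masked rows
    n_samples: int

    def variance(self, name: str) -> float:
        return float(self.components.loc[name, "mean"])


def _eigen_bases(kernels: KernelSet):
    bases = {}
    for name, K in kernels.items():
        lam, phi = np.linalg.eigh(K)
        if lam.min() < -PSD_TOL:
            raise ValueError(f"kernel {name} not PSD (min eigenvalue {lam.min():.3e})")
        keep = lam > 1e-10
        bases[name] = (phi[:, keep], lam[keep])
    return bases


def _ess(chain: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator."""
    x = np.asarray(chain, float)
    n = len(x)
    if n < 4 or x.std() == 0:
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (x @ x)
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def fit_gibbs(
    y,
    kernels: KernelSet,
    iters: int = 42000,
    burnin: int = 2000,
    thin: int = 5,
    seed: int = 0,
    fixed_variances: dict | None = None,
) -> PosteriorSummary:
    """Gibbs sampler for the multi-kernel model.

    ``y`` may contain NaN for responses to predict; those rows must
    still be covered by the kernels.  ``fixed_variances`` (name ->
    value, plus ``'residual'``) freezes variance components, which
    turns the sampler into a stochastic solver of the corresponding
    mixed-model equations (used for oracle-equivalence checks).
    """
    y = np.asarray(y, float)
    n = len(y)
    if kernels.n_obs != n:
        raise ValueError("kernel dimension does not match response length")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    names = kernels.names()
    if not names:
        raise ValueError("at least one kernel required")
    bases = _eigen_bases(kernels)
    rng = np.random.default_rng(seed)

    obs = np.isfinite(y)
    masked = ~obs
    vy = float(np.var(y[obs], ddof=1)) if obs.sum() > 1 else 1.0
    vy = max(vy, 1e-12)
    k_count = len(names)
    s0_k = 0.5 * vy / k_count * (PRIOR_DF + 2.0) / PRIOR_DF
    s0_e = 0.5 * vy * (PRIOR_DF + 2.0) / PRIOR_DF

    mu = float(np.mean(y[obs]))
    yf = np.where(obs, y, mu)
    u = {k: np.zeros(n) for k in names}
    total = np.zeros(n)
    sig2 = {k: 0.5 * vy / k_count for k in names}
    sig2_e = 0.5 * vy
    if fixed_variances:
        for k in names:
            if k in fixed_variances:
                sig2[k] = float(fixed_variances[k])
        if "residual" in fixed_variances:
            sig2_e = float(fixed_variances["residual"])

    kept = 0
    chains = {k: [] for k in names}
    chain_e, chain_mu = [], []
    fitted_sum = np.zeros(n)

    for it in range(iters):
        # data augmentation for masked responses
        if masked.any():
            yf[masked] = mu + total[masked] + rng.normal(0.0, np.sqrt(sig2_e), masked.sum())

        # mean
        r = yf - total
        mu = rng.normal(r.mean(), np.sqrt(sig2_e / n))

        for k in names:
            phi, lam = bases[k]
            resid_k = yf - mu - (total - u[k])
            at = phi.T @ resid_k
            var = 1.0 / (1.0 / sig2_e + 1.0 / (sig2[k] * lam))
            a = var * at / sig2_e + np.sqrt(var) * rng.standard_normal(len(lam))
            new_u = phi @ a
            total += new_u - u[k]
            u[k] = new_u
            if not (fixed_variances and k in fixed_variances):
                ss = float(np.sum(a * a / lam))
                df = PRIOR_DF + len(lam)
                sig2[k] = (PRIOR_DF * s0_k + ss) / rng.chisquare(df)

        if not (fixed_variances and "residual" in fixed_variances):
            e = yf - mu - total
            sig2_e = (PRIOR_DF * s0_e + float(e @ e)) / rng.chisquare(PRIOR_DF + n)

        if it >= burnin and (it - burnin) % thin == 0:
            kept += 1
            chain_mu.append(mu)
            chain_e.append(sig2_e)
            for k in names:
                chains[k].append(sig2[k])
            fitted_sum += mu + total

    fitted = fitted_sum / kept
    rows = []
    for k in names:
        c = np.array(chains[k])
        rows.append({"component": k, "mean": c.mean(), "sd": c.std(ddof=1), "ess": _ess(c)})
    ce = np.array(chain_e)
    rows.append({"component": "residual", "mean": ce.mean(), "sd": ce.std(ddof=1), "ess": _ess(ce)})
    comp = pd.DataFrame(rows).set_index("component")
    preds = pd.Series(fitted[masked], index=np.flatnonzero(masked))
    return PosteriorSummary(
        mu_hat=float(np.mean(chain_mu)),
        components=comp,
        fitted=fitted,
        predictions=preds,
        n_samples=kept,
    )


def blup_oracle(y, kernels: KernelSet, variances: dict):
    """Closed-form GLS/BLUP solution at fixed variance components.

    ``variances`` maps kernel names to their components plus
    ``'residual'``.  Rows of ``y`` that are NaN are predicted from the
    covariance between test and training rows.  Returns a dict with
    ``mu``, per-kernel effect vectors ``u`` (over all rows), ``fitted``
    and ``predictions``.
    """
    y = np.asarray(y, float)
    n = len(y)
    obs = np.isfinite(y)
    tr = np.flatnonzero(obs)
    if "residual" not in variances or variances["residual"] <= 0:
        raise ValueError("positive residual variance required")
    V = variances["residual"] * np.eye(len(tr))
    for k, K in kernels.items():
        V += variances.get(k, 0.0) * K[np.ix_(tr, tr)]
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phenotypic covariance") from exc
    ones = np.ones(len(tr))
    mu = float(ones @ Vi @ y[tr]) / float(ones @ Vi @ ones)
    r = Vi @ (y[tr] - mu)
    u = {k: variances.get(k, 0.0) * K[:, tr] @ r for k, K in kernels.items()}
    fitted = mu + np.sum(list(u.values()), axis=0) if u else np.full(n, mu)
    return {
        "mu": mu,
        "u": u,
        "fitted": fitted,
        "predictions": pd.Series(fitted[~obs], index=np.flatnonzero(~obs)),
    }


def predict_masked(
    kernels: KernelSet,
    y_masked,
    method: str = "gibbs",
    variances: dict | None = None,
    iters: int = 4000,
    burnin: int = 500,
    thin: int = 2,
    seed: int = 0,
) -> pd.Series:
    """Predict the masked (NaN) entries of ``y_masked``.

    ``method='gibbs'`` runs the full sampler (variances estimated);
    ``method='blup'`` uses the closed-form oracle at the supplied
    ``variances``.
    """
    y_masked = np.asarray(y_masked, float)
    if not np.isnan(y_masked).any():
        raise ValueError("no masked responses to predict")
    if method == "gibbs":
        post = fit_gibbs(y_masked, kernels, iters=iters, burnin=burnin, thin=thin, seed=seed)
        return post.predictions
    if method == "blup":
        if variances is None:
            raise ValueError("method='blup' requires variance components")
        return blup_oracle(y_masked, kernels, variances)["predictions"]
    raise ValueError(f"unknown method {method!r}")
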