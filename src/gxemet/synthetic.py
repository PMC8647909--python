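"""Synthetic multi-environment-trial generator with known ground truth.

Everything downstream — stage-1 BLUEs, genotype QC, weather QC,
environmental covariates, reaction-norm kernels, cross-validation —
can be exercised on data from this module, whose generative model is
the additive variance-component decomposition

    y_ij = mu + E_i + g_j + w_ij + gw_ij + gE_ij + rep + eps

with g_j a linear combination of marker dosages (IID marker effects),
w_ij a random regression on the standardized environmental covariates,
gw_ij a sparse marker-by-covariate interaction, and gE_ij drawn per
environment with covariance G.  Each realized term is rescaled so its
sample variance equals the configured component exactly, and all
realized terms are recorded in a :class:`TruthRecord`.

Weather is generated from a site-specific seasonal sinusoid with AR(1)
daily anomalies, a Markov-chain rainfall occurrence process with gamma
amounts, and bounded noise for humidity, wind and cloudiness; the
30-minute expansion is exactly consistent with the daily skeleton so
the sub-daily -> daily aggregation path can be validated against it.
"""

from __future__ import annotations

import datetime as dt
import itertools
import json
import logging
import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import covariates as ec
from .genotypes import MarkerMatrix, _center_scale

log = logging.getLogger(__name__)

DEFAULT_VARIANCES = {
    "sigma2_E": 2.0,
    "sigma2_S": 0.0,
    "sigma2_Y": 0.0,
    "sigma2_g": 0.5,
    "sigma2_w": 0.5,
    "sigma2_gw": 0.3,
    "sigma2_gE": 0.3,
    "sigma2_rep": 0.05,
    "sigma2_resid": 1.0,
}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic MET.

    Defaults give a desk-scale trial network: 40 inbred parents, 80
    single-cross hybrids, 4 sites x 4 years, two replicates, an
    environment-dominated variance decomposition typical of maize
    yield trials (trait units Mg/ha), and GBS-like marker properties.
    """

    n_inbreds: int = 40
    n_markers: int = 400
    n_hybrids: int = 80
    n_sites: int = 4
    n_years: int = 4
    n_reps: int = 2
    variance_components: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCES))
    mu: float = 9.5
    missing_rate: float = 0.0
    het_rate: float = 0.0
    multiallelic_rate: float = 0.0
    maf_mean: float = 0.3
    fault_rates: dict = field(default_factory=dict)
    hybrid_year_fraction: float = 0.5
    season_days: int = 220
    thermal_req_mean: float = 900.0
    thermal_req_sd: float = 60.0
    gdd_base: float = 10.0
    n_outlier_plots: int = 0
    outlier_shift_sd: float = 6.0
    trait: str = "grain_yield"
    seed: int = 0

    def __post_init__(self):
        vc = dict(DEFAULT_VARIANCES)
        vc.update(self.variance_components)
        self.variance_components = vc
        for k, v in vc.items():
            if v < 0:
                raise ValueError(f"variance component {k} must be nonnegative")
        for name in ("missing_rate", "het_rate", "multiallelic_rate", "hybrid_year_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth realized by one simulation."""

    marker_effects: np.ndarray
    true_components: dict
    realized_components: dict
    silking_thermal_requirement: pd.Series
    environment_effects: pd.Series
    terms: pd.DataFrame | None = None  # per-observation realized terms

    def to_json(self, path) -> None:
        payload = {
            "marker_effects": list(map(float, self.marker_effects)),
            "true_components": self.true_components,
            "realized_components": self.realized_components,
            "silking_thermal_requirement": self.silking_thermal_requirement.to_dict(),
            "environment_effects": self.environment_effects.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class ClimateParams:
    """Site-level climate for the weather generator."""

    site: str
    latitude: float = 42.0
    longitude: float = -93.0
    elevation: float = 300.0
    temp_mean: float = 12.0  # annual mean (degC)
    temp_amplitude: float = 14.0  # seasonal half-range
    diurnal_range: float = 10.0
    ar1: float = 0.7
    temp_noise_sd: float = 2.0
    rain_freq: float = 0.3
    rain_mean_mm: float = 8.0
    rh_mean: float = 65.0
    wind_mean: float = 2.5
    solar_peak: float = 800.0  # clear-sky noon W/m2


@dataclass
class SoilProfile:
    site: str
    sand: float
    silt: float
    clay: float
    om: float


def default_sites(n_sites: int) -> list[ClimateParams]:
    """A north-south gradient of sites: higher latitude, cooler and later."""
    out = []
    for i in range(n_sites):
        frac = i / max(n_sites - 1, 1)
        out.append(
            ClimateParams(
                site=f"S{i + 1}",
                latitude=45.0 - 7.0 * frac,
                longitude=-96.0 + 8.0 * frac,
                elevation=350.0 - 150.0 * frac,
                temp_mean=10.5 + 4.5 * frac,
                rain_freq=0.25 + 0.1 * frac,
                rh_mean=60.0 + 10.0 * frac,
            )
        )
    return out


# ---------------------------------------------------------------------------
# genotypes

def simulate_inbred_genotypes(cfg: SimulationConfig) -> MarkerMatrix:
    """GBS-like inbred panel: block LD, target MAF, injected heterozygous
    and missing calls, and optionally multi-allelic sites (to give the
    biallelic filter work)."""
    if cfg.n_inbreds < 2 or cfg.n_markers < 1:
        raise ValueError("need at least 2 inbreds and 1 marker")
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_inbreds, cfg.n_markers
    lo = max(0.05, cfg.maf_mean - 0.2)
    hi = min(0.5, cfg.maf_mean + 0.2)

    block = 10
    # markers within an LD block share a base frequency (plus jitter) so
    # the shared latent draw below yields genuinely correlated dosages
    n_blocks = math.ceil(p / block)
    base = rng.uniform(lo, hi, size=n_blocks)
    freq = np.clip(
        np.repeat(base, block)[:p] + rng.uniform(-0.04, 0.04, size=p), 0.03, 0.97
    )

    dosage = np.empty((n, p))
    for b0 in range(0, p, block):
        b1 = min(b0 + block, p)
        # shared latent uniform per block creates high intra-block LD;
        # per-marker mutation breaks perfect correlation
        z = rng.uniform(size=n)[:, None]
        alleles = (z < freq[b0:b1][None, :]).astype(float)
        mut = rng.uniform(size=(n, b1 - b0)) < 0.15
        indep = (rng.uniform(size=(n, b1 - b0)) < freq[b0:b1][None, :]).astype(float)
        alleles = np.where(mut, indep, alleles)
        dosage[:, b0:b1] = 2.0 * alleles

    if cfg.het_rate > 0:
        het = rng.uniform(size=dosage.shape) < cfg.het_rate
        dosage[het] = 1.0
    if cfg.missing_rate > 0:
        miss = rng.uniform(size=dosage.shape) < cfg.missing_rate
        dosage[miss] = np.nan

    allele_counts = np.full(p, 2, dtype=int)
    if cfg.multiallelic_rate > 0:
        tri = rng.uniform(size=p) < cfg.multiallelic_rate
        allele_counts[tri] = 3

    n_chrom = 10
    per = math.ceil(p / n_chrom)
    chrom = np.repeat(np.arange(1, n_chrom + 1), per)[:p]
    pos = np.concatenate([np.arange(1, (chrom == c).sum() + 1) * 1000 for c in np.unique(chrom)])
    return MarkerMatrix(
        sample_ids=[f"I{i + 1:03d}" for i in range(n)],
        marker_ids=[f"M{j + 1:05d}" for j in range(p)],
        dosage=dosage,
        chrom=chrom,
        pos=pos,
        allele_counts=allele_counts,
    )


def plan_hybrids(inbreds: MarkerMatrix, n_hybrids: int, seed: int) -> pd.DataFrame:
    """Sample unique unordered parent pairs (no selfs) as single-cross hybrids."""
    n = inbreds.n_samples
    pairs = list(itertools.combinations(range(n), 2))
    if n_hybrids > len(pairs):
        raise ValueError(f"requested {n_hybrids} hybrids but only {len(pairs)} crosses possible")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=n_hybrids, replace=False)
    rows = []
    for h, idx in enumerate(sorted(chosen)):
        i, j = pairs[idx]
        rows.append(
            {
                "hybrid": f"H{h + 1:04d}",
                "parent1": inbreds.sample_ids[i],
                "parent2": inbreds.sample_ids[j],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# weather

_HOURS = np.arange(48) * 0.5  # half-hour marks


def _stable_hash(s: str) -> int:
    """Process-independent string hash (Python's hash() is salted)."""
    return zlib.crc32(s.encode()) % (2**31)


def _season_dates(year: int, n_days: int) -> pd.DatetimeIndex:
    start = dt.date(year, 4, 1)
    return pd.date_range(start, periods=n_days, freq="D")


def _weather_skeleton(params: ClimateParams, year: int, rng: np.random.Generator, n_days: int) -> pd.DataFrame:
    """Daily weather core; the 30-min expansion is exactly consistent with it."""
    dates = _season_dates(year, n_days)
    doy = dates.dayofyear.to_numpy(float)
    seasonal = params.temp_mean + params.temp_amplitude * np.cos(2 * np.pi * (doy - 200.0) / 365.0)
    anom = np.empty(n_days)
    a = 0.0
    innov = rng.normal(0.0, params.temp_noise_sd, size=n_days)
    for d in range(n_days):
        a = params.ar1 * a + innov[d]
        anom[d] = a
    tmean = seasonal + anom
    half_range = params.diurnal_range / 2.0 + rng.normal(0, 0.5, size=n_days).clip(-2, 2)
    half_range = np.maximum(half_range, 1.0)
    tmax = tmean + half_range
    tmin = tmean - half_range

    wet = np.zeros(n_days, dtype=bool)
    amounts = np.zeros(n_days)
    p_prev = params.rain_freq
    for d in range(n_days):
        p = min(0.95, params.rain_freq * (1.6 if d > 0 and wet[d - 1] else 0.85))
        wet[d] = rng.uniform() < p
        if wet[d]:
            amounts[d] = rng.gamma(1.5, params.rain_mean_mm / 1.5)

    rh = np.clip(params.rh_mean + 8.0 * wet + rng.normal(0, 5, size=n_days), 30.0, 92.0)
    wind = np.abs(rng.normal(params.wind_mean, 0.8, size=n_days)) + 0.5
    cloud = np.where(wet, rng.uniform(0.25, 0.6, size=n_days), rng.uniform(0.75, 1.0, size=n_days))

    # daily solar = exact half-hourly integral of the clear-sky sine profile
    daylen = np.array([_day_hours(params.latitude, d) for d in doy])
    solar = np.empty(n_days)
    for d in range(n_days):
        prof = _solar_profile(params.solar_peak, daylen[d]) * cloud[d]
        solar[d] = prof.sum() * 1800.0 / 1e6
    df = pd.DataFrame(
        {
            "tmax": tmax,
            "tmin": tmin,
            "tmean": (tmax + tmin) / 2.0,
            "precip": amounts,
            "rh": rh,
            "solar": solar,
            "wind": wind,
            "cloud": cloud,
            "daylen": daylen,
        },
        index=dates,
    )
    return df


def _day_hours(latitude: float, doy: float) -> float:
    phi = math.radians(latitude)
    decl = 0.409 * math.sin(2.0 * math.pi / 365.0 * doy - 1.39)
    ws = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(decl))))
    return 24.0 / math.pi * ws

def _solar_profile(peak: float, daylen: float) -> np.ndarray:
    sunrise = 12.0 - daylen / 2.0
    sunset = 12.0 + daylen / 2.0
    frac = (_HOURS - sunrise) / (sunset - sunrise)
    return np.where((frac > 0) & (frac < 1), peak * np.sin(np.pi * frac), 0.0)


def simulate_daily_series(params: ClimateParams, year: int, seed: int, n_days: int = 200) -> pd.DataFrame:
    """Daily weather in the weather-engine format (all QC flags False)."""
    rng = np.random.default_rng([seed, year, _stable_hash(params.site)])
    core = _weather_skeleton(params, year, rng, n_days)
    out = core[["tmax", "tmin", "tmean", "precip", "rh", "solar", "wind"]].copy()
    out.index.name = "date"
    for f in ("count", "range", "persistence", "consistency", "imputed"):
        out[f"flag_{f}"] = False
    return out


def simulate_daily_weather(
    params: ClimateParams,
    year: int,
    seed: int,
    n_days: int = 200,
    fault_rates: dict | None = None,
) -> pd.DataFrame:
    """30-minute station records (long format), optionally with injected
    sensor faults: ``stuck`` (zero intra-day variance), ``gap``
    (missing records) and ``spike`` (out-of-range values)."""
    if n_days < 120:
        raise ValueError("season length must be >= 120 days")
    rng = np.random.default_rng([seed, year, _stable_hash(params.site)])
    core = _weather_skeleton(params, year, rng, n_days)
    faults = {"stuck": 0.0, "gap": 0.0, "spike": 0.0}
    faults.update(fault_rates or {})
    frng = np.random.default_rng([seed + 1, year])

    recs = []
    for date, row in core.iterrows():
        ts = date + pd.to_timedelta(_HOURS, unit="h")
        temp = row["tmean"] + (row["tmax"] - row["tmean"]) * np.sin(2 * np.pi * (_HOURS - 9.0) / 24.0)
        rh = np.clip(row["rh"] - 8.0 * np.sin(2 * np.pi * (_HOURS - 9.0) / 24.0), 0.0, 100.0)
        wind = row["wind"] + 0.4 * np.sin(2 * np.pi * (_HOURS - 6.0) / 24.0)
        solar = _solar_profile(params.solar_peak, row["daylen"]) * row["cloud"]
        rain = np.zeros(48)
        if row["precip"] > 0:
            slots = frng.choice(48, size=4, replace=False)
            share = frng.dirichlet(np.ones(4))
            rain[slots] = row["precip"] * share
        day_vars = {"temperature": temp, "rh": rh, "rainfall": rain, "solar": solar, "wind": wind}
        for var, vals in day_vars.items():
            vals = vals.astype(float).copy()
            keep = np.ones(48, dtype=bool)
            if var != "rainfall" and frng.uniform() < faults["stuck"]:
                vals[:] = vals.mean()
            if frng.uniform() < faults["gap"]:
                keep = frng.uniform(size=48) < 0.4
            if var != "rainfall" and frng.uniform() < faults["spike"]:
                vals[frng.integers(48)] = {"temperature": 80.0, "rh": 150.0, "solar": 2000.0, "wind": 90.0}[var]
            for t, v, k in zip(ts, vals, keep):
                if k:
                    recs.append((params.site, t, var, v))
    return pd.DataFrame(recs, columns=["site", "timestamp", "variable", "value"])


# ---------------------------------------------------------------------------
# soil & phenology

def simulate_soil(site: str, seed: int, om_range: tuple = (0.5, 8.0)) -> SoilProfile:
    """Dirichlet texture composition (sums to 100) and bounded organic matter."""
    rng = np.random.default_rng([seed, _stable_hash(site)])
    comp = rng.dirichlet([4.0, 3.0, 2.0]) * 100.0
    om = float(rng.uniform(*om_range))
    return SoilProfile(site=site, sand=float(comp[0]), silt=float(comp[1]), clay=float(comp[2]), om=om)


def simulate_phenology(
    thermal_requirement: float,
    daily: pd.DataFrame,
    planting: dt.date,
    base: float = 10.0,
) -> dt.date:
    """First day on which cumulative growing degrees from planting reach
    the hybrid's thermal requirement (50% silking date)."""
    from .weather import daily_growing_degrees

    planting = pd.Timestamp(planting)
    days = daily.index[daily.index > planting]
    if len(days) == 0:
        raise ValueError("no weather after planting")
    sub = daily.loc[days]
    gdd = daily_growing_degrees(sub["tmin"].to_numpy(), sub["tmax"].to_numpy(), base=base)
    cum = np.cumsum(gdd)
    hit = np.flatnonzero(cum >= thermal_requirement)
    if len(hit) == 0:
        raise ValueError(
            f"season too short: requirement {thermal_requirement:.0f} GDD never reached"
        )
    return days[hit[0]].date()


# ---------------------------------------------------------------------------
# trial design & phenotypes

def make_design(
    hybrids: list,
    sites: list,
    years: list,
    n_reps: int,
    hybrid_year_fraction: float,
    seed: int,
    planting_by_env: dict,
) -> pd.DataFrame:
    """Allocate hybrids to a subset of years (unbalanced, as in real MET
    networks, and required for genotype-disjoint CV00 splits)."""
    rng = np.random.default_rng(seed)
    n_assigned = max(1, round(hybrid_year_fraction * len(years)))
    rows = []
    for h in hybrids:
        hy = sorted(rng.choice(len(years), size=n_assigned, replace=False))
        for yi in hy:
            year = years[yi]
            for site in sites:
                env = f"{site}_{year}"
                for rep in range(1, n_reps + 1):
                    rows.append(
                        {
                            "environment": env,
                            "site": site,
                            "year": year,
                            "hybrid": h,
                            "replicate": rep,
                            "planting_date": planting_by_env[env],
                        }
                    )
    return pd.DataFrame(rows)


def _rescale(x: np.ndarray, target_var: float) -> np.ndarray:
    v = x.var(ddof=1) if len(x) > 1 else 0.0
    if target_var <= 0 or v <= 0:
        return np.zeros_like(x)
    return x * math.sqrt(target_var / v)


def simulate_phenotypes(
    cfg: SimulationConfig,
    genotypes: MarkerMatrix,
    W: pd.DataFrame,
    design: pd.DataFrame,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate plot phenotypes from the variance-component truth.

    ``W`` must be the standardized covariate matrix indexed by
    ``(environment, hybrid)`` for every observation in ``design``.
    Each realized term is rescaled to hit its configured component
    exactly; realized variances are recorded in the truth record.
    """
    vc = cfg.variance_components
    rng = np.random.default_rng(cfg.seed + 104729)
    obs = design[["environment", "site", "year", "hybrid"]].drop_duplicates().reset_index(drop=True)
    key = pd.MultiIndex.from_frame(obs[["environment", "hybrid"]])
    if not key.isin(W.index).all():
        raise ValueError("W rows misaligned with design observations")
    Wm = W.loc[key].to_numpy(float)
    n_obs, q = Wm.shape

    hybrids = list(genotypes.sample_ids)
    hidx = {h: i for i, h in enumerate(hybrids)}
    if not obs["hybrid"].isin(hidx).all():
        raise ValueError("design references hybrids absent from genotype matrix")
    x_std, _ = _center_scale(genotypes.dosage)
    nh, p = x_std.shape
    obs_h = obs["hybrid"].map(hidx).to_numpy()

    envs = sorted(obs["environment"].unique())
    env_eff = pd.Series(_rescale(rng.normal(size=len(envs)), vc["sigma2_E"]), index=envs)
    sites = sorted(obs["site"].unique())
    years = sorted(obs["year"].unique())
    site_eff = pd.Series(_rescale(rng.normal(size=len(sites)), vc["sigma2_S"]), index=sites)
    year_eff = pd.Series(_rescale(rng.normal(size=len(years)), vc["sigma2_Y"]), index=years)

    b = rng.normal(size=p) / math.sqrt(p)
    g_h = x_std @ b
    v_obs = g_h[obs_h].var(ddof=1)
    scale = math.sqrt(vc["sigma2_g"] / v_obs) if vc["sigma2_g"] > 0 and v_obs > 0 else 0.0
    b = b * scale
    g_h = g_h * scale

    gamma = rng.normal(size=q) / math.sqrt(max(q, 1))
    w_obs = _rescale(Wm @ gamma, vc["sigma2_w"])

    # sparse marker-by-covariate interaction: gw = sum_q W_q * (x . c_q)
    c = rng.normal(size=(q, p)) * (rng.uniform(size=(q, p)) < 0.1)
    inter_h = x_std @ c.T  # hybrids x q
    gw_obs = _rescale((Wm * inter_h[obs_h]).sum(axis=1), vc["sigma2_gw"])

    # gE: independent N(0, G) draws per environment
    G = x_std @ x_std.T / p
    evals, evecs = np.linalg.eigh(G)
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    ge_h_by_env = {e: L @ rng.normal(size=nh) for e in envs}
    ge_obs = np.array([ge_h_by_env[e][j] for e, j in zip(obs["environment"], obs_h)])
    ge_obs = _rescale(ge_obs, vc["sigma2_gE"])

    terms = pd.DataFrame(
        {
            "E": env_eff[obs["environment"]].to_numpy()
            + site_eff[obs["site"]].to_numpy()
            + year_eff[obs["year"]].to_numpy(),
            "g": g_h[obs_h],
            "w": w_obs,
            "gw": gw_obs,
            "gE": ge_obs,
        },
        index=key,
    )
    signal = cfg.mu + terms.sum(axis=1)
    obs_signal = pd.Series(signal.to_numpy(), index=key)

    reps = design[["environment", "replicate"]].drop_duplicates()
    rep_eff = {
        (r.environment, r.replicate): v
        for r, v in zip(
            reps.itertuples(index=False),
            _rescale(rng.normal(size=len(reps)), vc["sigma2_rep"]),
        )
    }
    plots = design.copy()
    plot_key = pd.MultiIndex.from_frame(plots[["environment", "hybrid"]])
    resid = _rescale(rng.normal(size=len(plots)), vc["sigma2_resid"])
    plots["trait"] = (
        obs_signal.loc[plot_key].to_numpy()
        + np.array([rep_eff[(e, r)] for e, r in zip(plots["environment"], plots["replicate"])])
        + resid
    )
    plots["is_outlier"] = False
    if cfg.n_outlier_plots > 0:
        idx = rng.choice(len(plots), size=min(cfg.n_outlier_plots, len(plots)), replace=False)
        shift = cfg.outlier_shift_sd * math.sqrt(max(vc["sigma2_resid"], 1e-12))
        sign = rng.choice([-1.0, 1.0], size=len(idx))
        plots.loc[plots.index[idx], "trait"] += sign * shift
        plots.loc[plots.index[idx], "is_outlier"] = True

    realized = {
        "sigma2_E": float(terms["E"].var(ddof=1)),
        "sigma2_g": float(terms["g"].var(ddof=1)),
        "sigma2_w": float(terms["w"].var(ddof=1)),
        "sigma2_gw": float(terms["gw"].var(ddof=1)),
        "sigma2_gE": float(terms["gE"].var(ddof=1)),
        "sigma2_resid": float(np.var(resid, ddof=1)),
    }
    truth = TruthRecord(
        marker_effects=b,
        true_components={k: float(v) for k, v in vc.items()},
        realized_components=realized,
        silking_thermal_requirement=pd.Series(dtype=float),
        environment_effects=env_eff,
        terms=terms,
    )
    return plots, truth


# ---------------------------------------------------------------------------
# end-to-end bundle

@dataclass
class MetDataset:
    """A complete synthetic MET: everything the pipeline consumes."""

    config: SimulationConfig
    inbreds: MarkerMatrix
    pedigree: pd.DataFrame
    hybrids: MarkerMatrix
    climate: list
    daily: dict  # environment -> derived daily weather
    soil: dict  # site -> SoilProfile
    design: pd.DataFrame
    plots: pd.DataFrame
    silking: pd.Series  # (environment, hybrid) -> date
    W_raw: pd.DataFrame  # unstandardized EC matrix, (environment, hybrid) index
    W: pd.DataFrame  # globally standardized EC matrix used by the generator
    truth: TruthRecord

    def soil_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.soil.values()]).set_index("site")

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": [c.site for c in self.climate],
                "longitude": [c.longitude for c in self.climate],
                "latitude": [c.latitude for c in self.climate],
            }
        ).set_index("site")


def simulate_met(cfg: SimulationConfig, include_coords: bool = True) -> MetDataset:
    """Generate a full synthetic MET dataset with aligned components.

    Inbred genotypes -> in-silico hybrids (parental means), per
    site x year daily weather, soil, GDD-driven silking dates, the
    Table-style covariate matrix W and plot phenotypes from the
    variance-component truth.
    """
    rng = np.random.default_rng(cfg.seed)
    inbreds = simulate_inbred_genotypes(cfg)
    pedigree = plan_hybrids(inbreds, cfg.n_hybrids, cfg.seed + 1)
    pidx = {s: i for i, s in enumerate(inbreds.sample_ids)}
    dos = np.asarray(
        [
            (np.nan_to_num(inbreds.dosage[pidx[r.parent1]]) + np.nan_to_num(inbreds.dosage[pidx[r.parent2]])) / 2.0
            for r in pedigree.itertuples(index=False)
        ]
    )
    dos = np.clip(np.round(dos), 0.0, 2.0)
    hybrids = MarkerMatrix(
        sample_ids=list(pedigree["hybrid"]),
        marker_ids=list(inbreds.marker_ids),
        dosage=dos,
        chrom=inbreds.chrom.copy(),
        pos=inbreds.pos.copy(),
        allele_counts=inbreds.allele_counts.copy(),
    )

    climate = default_sites(cfg.n_sites)
    years = list(range(2014, 2014 + cfg.n_years))
    daily: dict[str, pd.DataFrame] = {}
    planting_by_env: dict[str, dt.date] = {}
    prng = np.random.default_rng(cfg.seed + 2)
    for cp in climate:
        for year in years:
            env = f"{cp.site}_{year}"
            series = simulate_daily_series(cp, year, cfg.seed, n_days=cfg.season_days)
            daily[env] = ec.derive_daily(series, cp.latitude, cp.elevation, base=cfg.gdd_base)
            planting_by_env[env] = (
                pd.Timestamp(dt.date(year, 4, 20)) + pd.Timedelta(days=int(prng.integers(0, 11)))
            ).date()

    design = make_design(
        list(pedigree["hybrid"]),
        [c.site for c in climate],
        years,
        cfg.n_reps,
        cfg.hybrid_year_fraction,
        cfg.seed + 3,
        planting_by_env,
    )

    req = pd.Series(
        np.maximum(rng.normal(cfg.thermal_req_mean, cfg.thermal_req_sd, size=cfg.n_hybrids), 200.0),
        index=list(pedigree["hybrid"]),
    )
    obs = design[["environment", "hybrid"]].drop_duplicates()
    silking = {}
    cov_rows = {}
    cov_cache: dict[tuple, dict] = {}
    for env, hyb in obs.itertuples(index=False):
        planting = planting_by_env[env]
        silk = simulate_phenology(req[hyb], daily[env], planting, base=cfg.gdd_base)
        silking[(env, hyb)] = silk
        ck = (env, silk)
        if ck not in cov_cache:
            windows = ec.stage_windows(planting, silk)
            cov_cache[ck] = ec.stage_covariates(daily[env], windows)
        cov_rows[(env, hyb)] = cov_cache[ck]
    silking = pd.Series(silking)
    silking.index.names = ["environment", "hybrid"]
    stage_covs = pd.DataFrame.from_dict(cov_rows, orient="index")
    stage_covs.index = pd.MultiIndex.from_tuples(stage_covs.index, names=["environment", "hybrid"])

    soil = {cp.site: simulate_soil(cp.site, cfg.seed + 4) for cp in climate}
    env_site = {f"{cp.site}_{y}": cp.site for cp in climate for y in years}
    soil_rows = pd.DataFrame(
        [
            {
                "SandProp.SC": soil[env_site[e]].sand,
                "Silt.Prop.SC": soil[env_site[e]].silt,
                "ClayProp.SC": soil[env_site[e]].clay,
                "OM.SC": soil[env_site[e]].om,
            }
            for e, _ in stage_covs.index
        ],
        index=stage_covs.index,
    )
    coords_rows = None
    if include_coords:
        by_site = {c.site: (c.longitude, c.latitude) for c in climate}
        coords_rows = pd.DataFrame(
            [
                {"longitude": by_site[env_site[e]][0], "latitude": by_site[env_site[e]][1]}
                for e, _ in stage_covs.index
            ],
            index=stage_covs.index,
        )
    W_raw = ec.assemble_W(stage_covs, soil_rows, coords_rows, trait=cfg.trait)
    W = ec.ECScaler().fit_transform(W_raw)

    plots, truth = simulate_phenotypes(cfg, hybrids, W, design)
    truth.silking_thermal_requirement = req
    plots["silking_date"] = [silking[(e, h)] for e, h in zip(plots["environment"], plots["hybrid"])]

    return MetDataset(
        config=cfg,
        inbreds=inbreds,
        pedigree=pedigree,
        hybrids=hybrids,
        climate=climate,
        daily=daily,
        soil=soil,
        design=design,
        plots=plots,
        silking=silking,
        W_raw=W_raw,
        W=W,
        truth=truth,
    )


def write_dataset(ds: MetDataset, outdir) -> None:
    """Write the bundle as plain-text artifacts (CSV + JSON truth)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.plots.to_csv(out / "plots.csv", index=False)
    ds.hybrids.to_frame().to_csv(out / "hybrid_genotypes.csv")
    ds.inbreds.to_frame().to_csv(out / "inbred_genotypes.csv")
    ds.pedigree.to_csv(out / "pedigree.csv", index=False)
    ds.W_raw.to_csv(out / "ec_matrix_raw.csv")
    ds.soil_frame().to_csv(out / "soil.csv")
    long = []
    for env, df in ds.daily.items():
        d = df.reset_index().melt(id_vars="date", var_name="variable", value_name="value")
        d.insert(0, "environment", env)
        long.append(d)
    pd.concat(long).to_csv(out / "daily_weather.csv", index=False)
    ds.truth.to_json(out / "truth.json")
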