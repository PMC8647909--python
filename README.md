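# gxemet

Genomic × environmental prediction for maize multi-environment trials
(MET): growth-stage environmental covariates from raw weather,
reaction-norm genomic prediction with genotype-by-environment
interaction, gradient-boosting comparators, and forward
cross-validation for untested years, sites and genotypes.

## Who this is for

Quantitative geneticists and breeding analysts who want to predict
hybrid performance in environments that were never phenotyped — next
year's trials, a new site, or newly developed crosses — by combining
marker data with the weather and soil conditions each hybrid actually
experienced. Everything runs end-to-end on a built-in synthetic MET
generator with known ground truth, so the full pipeline is testable
without any external download; the same interfaces accept real
plot/genotype/weather tables in CSV (or VCF for genotypes).

## The model

Phenotypes are analyzed in two stages. Stage 1 fits, per environment
(site × year), the model `Y_ij = μ + G_i + R_j + ε_ij` with genotype
fixed and replicate random (exact profiled REML on the variance ratio),
yielding one BLUE per hybrid per environment; plots with
|studentized conditional residual| > 3 are removed and the BLUEs refit,
and replicates planted ≥ 7 days apart are treated as distinct,
unreplicated environments.

Stage 2 is a family of multi-kernel linear random-effects (reaction
norm) models on the BLUEs, up to the full

```
y_ij = μ + E_i + g_j + w_ij + gw_ij + gE_ij + ε_ij
```

with `g ~ N(0, G σ²_g)`, `G = XX′/p` the genomic relationship matrix
from centered/standardized dosages; `w ~ N(0, Ω σ²_w)` a random
regression on the standardized environmental covariate matrix **W**
(`Ω ∝ WW′`); and interactions as Hadamard products of expanded kernels,
e.g. `gE ~ N(0, [Z_g G Z_g′] ∘ [Z_E Z_E′] σ²_gE)` and
`gw ~ N(0, [Z_g G Z_g′] ∘ Ω σ²_gw)`. Fitting is Bayesian: a Gibbs
sampler with eigendecomposition reparameterization per kernel,
scaled-inverse-χ² priors on variance components, data augmentation for
masked responses, plus a closed-form BLUP oracle used for validation.

**W** holds 13 weather covariates (precipitation, temperature means and
extremes, growing degree days base 10 °C via the Baskerville–Emin sine
method, photothermal time, heat-stress frequencies and sums, FAO-56
Penman–Monteith ET₀, water balance, solar radiation) for each of three
phenology-anchored growth stages — vegetative (planting → silking−7 d),
flowering (silking−7 d → silking+14 d), grain filling (the next
65 days) — plus four soil-composition covariates and optionally the
site coordinates.

Machine-learning comparators (elastic net, XGBoost, LightGBM) consume
marker principal components, **W**, year indicators and coordinates,
with Gaussian-process Bayesian hyperparameter tuning (expected
improvement, inner 5-fold × 2-repeat CV) inside an outer forward CV —
CV0-Year/Site masks a whole year or site, CV00 additionally removes the
tested genotypes from training. Accuracy is the per-environment Pearson
correlation, combined across environments by inverse-sampling-variance
weighting, `r_w = Σ r_j/V(r_j) / Σ 1/V(r_j)` with
`V(r_j) = (1−r_j²)/(n_j−2)`. Fitted tree ensembles are interpreted with
normalized gain importance and Friedman partial dependence profiles;
tuning logs feed a random-forest fANOVA of hyperparameter importance.

## Worked example

```python
from gxemet.pipeline import ExperimentConfig, run_experiment, compare_models
from gxemet.synthetic import SimulationConfig

cfg = ExperimentConfig(
    seed=42,
    lre_models=["G+E", "G+E+W+GxW+GxE"],
    ml_models=["gbdt_a"],
    schemes=["CV0-Year", "CV00-Year"],
    simulation=SimulationConfig(seed=42, n_hybrids=60, n_sites=3, n_years=4,
                                n_inbreds=30, n_markers=200,
                                hybrid_year_fraction=0.5),
)
bundle = run_experiment(cfg)
table = compare_models(bundle["summary"])
print(table[["scheme", "model", "r_w", "pct_change_vs_baseline"]].round(3).to_string(index=False))
```

prints

```
   scheme         model   r_w  pct_change_vs_baseline
 CV0-Year G+E+W+GxW+GxE 0.669                  20.464
 CV0-Year           G+E 0.556                   0.000
 CV0-Year        gbdt_a 0.532                  -4.238
CV00-Year G+E+W+GxW+GxE 0.604                   8.008
CV00-Year           G+E 0.560                   0.000
CV00-Year        gbdt_a 0.297                 -46.907
```

`r_w` is the weighted predictive ability of each model under each
forward scheme on this synthetic MET (60 hybrids, 12 environments,
genotype-by-covariate interaction present). The covariate-aware
reaction-norm model (`G+E+W+GxW+GxE`) improves on the genomic baseline
in both schemes — most usefully in CV00-Year, where neither the year
nor the genotypes were ever observed; the gradient-boosting model is
competitive when tested genotypes have records elsewhere (CV0) but
needs more data than this small example to exploit the interaction for
brand-new genotypes.

A CLI mirrors the stages: `gxemet simulate`, `stage1`, `geno`,
`weather`, `run-all`, `evaluate` (see `gxemet --help`).

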