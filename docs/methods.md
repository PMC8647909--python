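# Methods notes

This note documents the modelling choices, default parameters, the
synthetic data-generating process, numerical policies, and the known
limitations of `gxemet`. It states no empirical results beyond what the
test suite and `scripts/acceptance.py` compute.

## Stage-1 phenotypic analysis

Each environment (site × year) is analyzed independently with
`Y_ij = μ + G_i + R_j + ε_ij`, genotype fixed, replicate random. The
single random effect admits an exact profile of the REML criterion on
the ratio λ = σ²_R/σ²_ε: for each λ the GLS estimates, the residual
variance and the restricted likelihood are closed-form, and λ is found
by bounded scalar minimization over log λ ∈ [log 1e−10, log 1e6] to
tolerance 1e−8, with an explicit comparison against the λ → 0 boundary.
Conditional residuals `ê = P y` (with `P` the REML projection matrix)
have covariance σ²_ε P, giving the studentization denominator exactly
rather than by approximation.

The outlier rule removes plots with |studentized conditional
residual| > 3 and refits once; the pass is not iterated, which keeps
the procedure deterministic and matches common practice. Replicates of
one experiment planted ≥ 7 days apart become distinct unreplicated
environments before any fitting; an unreplicated environment's BLUE is
its observation and its residuals are undefined (flagged).

## Genotype pipeline

Filters run in a fixed order: biallelic → taxa (coverage ≥ 70%,
heterozygosity ≤ 8%) → marker filters (polymorphic, missing ≤ 5%,
heterozygous ≤ 5%, MAF ≥ 2%) → imputation → LD pruning
(window 100 / step 5 / r² ≤ 0.99) → hybrid construction → final 2% MAF
on the hybrid panel. Boundary behavior is documented as strict on the
"more than" side: exactly 70% coverage and exactly 8% heterozygosity
are retained, MAF < 2% is removed.

Missing dosages are imputed by the per-marker mode (ties toward the
smaller dosage), with an optional k-nearest-haplotype refinement;
observed calls are never altered. Dedicated LD-aware imputation is out
of scope: imputation quality is not part of the evaluated claims here,
preservation of observed calls is.

LD pruning needs a deterministic removal rule (the field's standard
tools leave this to the implementation): within each window the most
correlated offending pair is broken by removing the lower-MAF member,
ties going to the larger column index. For window ≥ p this reduces to
all-pairs pruning, which is how the test oracle checks it.

The minor allele is defined on the parent panel at first computation
and frozen, so parent and hybrid codings cannot flip. Standardization
of X uses the sample SD (n−1 denominator); consequently the mean GRM
diagonal is exactly (n−1)/n.

## Weather engine

Sub-daily records pass four QC rules — record count (≥ 80% of the
nominal 48/day cadence), physical range (temperature −40…50 °C,
RH 0–100%, wind 0–40 m/s, rain 0–300 mm/day; configurable), persistence
(zero intra-day variability, tested for temperature/RH/wind; rainfall is
exempt because dry days legitimately have zero variance), and internal
consistency (tmin ≤ tmax) — before aggregation. A flagged variable-day
becomes missing; flags are never removed by later processing. Gap
filling is inverse-distance weighting (power 2) from neighbor stations;
spatio-temporal kriging is deliberately out of scope (IDW is
deterministic and dependency-free, and is the method of choice for wind
in any case). Wind is assumed measured at 2 m; `wind_to_2m` provides
the standard log-profile correction hook for other heights.

Derived variables: Baskerville–Emin single-sine growing degrees above a
10 °C base (closed-form integral of the positive part of the sine
curve; continuous across the base-crossing boundary), astronomical day
length from solar declination (|latitude| < 66.5° only), photothermal
time as GDD × day length, Tetens vapor pressure deficit, and FAO-56
Penman–Monteith ET₀ with albedo 0.23, the FAO net-longwave term, zero
soil heat flux at the daily step and elevation-derived psychrometric
constant.

## Environmental covariates

The three stage windows are half-open day intervals anchored on
planting and per-hybrid 50% silking: vegetative [planting, silking−7),
flowering [silking−7, silking+14), grain filling [silking+14,
silking+79). They tile the season with no double-counted days; the
grain-filling length is fixed at 65 days (physiological maturity).
Frequencies (FreqP5, FreqMaxT30, FreqMaxT35) are reported as fractions
of window days rather than raw counts so windows of different lengths
are comparable; thresholds are strict inequalities. Two hybrids with
identical silking dates in one environment share covariate rows (the
implementation caches on this).

For plant height the grain-filling weather columns are excluded (the
trait is measured shortly after flowering); the exclusion is a
trait → stage-mask table so new traits can declare their own masks.

Standardization of W is a fit/transform pair (`ECScaler`): in
cross-validation the scaling statistics come from training rows only
and are applied unchanged to test rows. Whether to standardize globally
or per training fold was an open choice; per-fold is mandatory for
honest forward prediction and is the implemented default in the
pipeline.

## Reaction-norm models

Kernels are built at observation level: indicator kernels for E/S/Y,
the expanded GRM for G, Ω = WW′/q for the covariate kernel (dividing by
the column count puts Ω's diagonal on the same ~1 scale as G's, making
variance components comparable; only proportionality is required), and
Hadamard products for interactions (PSD by the Schur product theorem,
which the tests verify numerically). Eigenvalues in (−1e−6, 0) are
clipped to zero; anything more negative is a hard error.

The Gibbs sampler reparameterizes each kernel through its
eigendecomposition, so the conditional posterior of the
eigen-coefficients is diagonal and one kernel update costs two
matrix–vector products. Variance components get conjugate
scaled-inverse-χ² updates with 5 prior degrees of freedom and scales
setting the prior modes to split half the phenotypic variance equally
among kernels (the residual prior mode gets the other half) — the
common default for Bayesian GBLUP software. Missing responses are
sampled by data augmentation; the posterior mean of μ + Σu on masked
rows is the prediction. Chain defaults are 42,000 iterations / 2,000
burn-in / thin 5; tests and the orchestrator's scaled-down mode use
4,000 / 500 / 2 (posterior means of fitted values converge much faster
than component posteriors). Effective sample sizes per component are
reported via the initial-positive-sequence estimator.

The sampler was validated two ways: frozen-variance runs agree with the
closed-form BLUP oracle (correlation > 0.999), and on a single-kernel
problem its posterior means match an exact two-dimensional grid
evaluation of the marginal posterior to three decimals. A consequence
worth knowing: for weakly identified components — notably σ²_w, whose
kernel Ω has few informative dimensions when covariates vary mostly
between environments and environments are few — the posterior is wide
and right-skewed, so its *mean* sits well above the generative value
even though the posterior itself is correct. This is a property of the
model/prior at desk scale, not a sampler defect; rank ordering of
components is preserved. Per-covariate effects (the γ vector) are never
materialized; they exist only through Ω.

## Machine-learning comparators

The feature table concatenates marker PCs, the standardized covariate
columns, one-hot year indicators and optional site coordinates (sites
enter as coordinates, never as high-cardinality labels). Zero-variance
columns are dropped and continuous columns standardized with
training-row statistics only. The default PC count follows the
top-PC screening logic at the panel's scale (capped at n−1); the
benchmark experiments use ~20% of the panel size.

Hyperparameter tuning is GP-based Bayesian optimization on a unit-cube
encoding: a 10-point Latin-hypercube initial design, then 30 expected-
improvement acquisitions over 512 random candidates per step, each
assignment scored by mean RMSE of a 5-fold × 2-repeat inner CV of the
outer training set. The tuned space (learning rate 1e−3…0.3
log-uniform, depth 1…12, trees 100…2000, min child weight 1…40,
feature fraction 0.3…1, row subsample 0.5…1) names the hyperparameters
the boosting literature considers load-bearing; remaining options stay
at backend defaults. The boosting engines themselves (XGBoost,
LightGBM) are consumed through a thin adapter — the contribution here
is the pipeline around them, not a reimplementation of histogram GBDT.

fANOVA hyperparameter importance fits a random forest to
(assignment → RMSE) and decomposes each tree's partition exactly over
the uniform unit cube: main-effect variances from per-dimension segment
marginals, pairwise interaction variances from the 2-D grid minus the
mains, shares averaged over trees. A Sobol pick-freeze Monte-Carlo
estimator over the same forest validates the exact path.

## Evaluation

CV0 holds out all observations of one year (or site); CV00 additionally
deletes every training observation of any genotype present in the test
set. Split construction is deterministic (units sorted). Environments
contribute a Pearson correlation only with n ≥ 3 (the sampling variance
(1−r²)/(n−2) is undefined below) and non-degenerate prediction
variance; |r| = 1 is capped at 0.9999 to keep inverse-variance weights
finite. Environments are site × year combinations after the 7-day
split rule. Evaluation assumes the target environment's realized
weather is known — prediction targets a new environment's outcome given
its conditions, not a weather forecast.

## Interpretation

Gain importance is total split gain normalized to sum one, with
provenance class tags. Partial dependence uses the Friedman estimator
on a 25-point quantile grid (quantiles avoid extrapolated regions);
profiles of standardized features can be mapped back to original units
via the stored scaler. When estimating the slope of a planted linear
effect from a tree-ensemble's profile, the benchmark fits the interior
of the grid: boosted trees flatten outside the dense data range, and
the tails would bias the slope of an otherwise faithful profile.
Importance of strongly collinear features is fundamentally
unidentifiable — gain splits arbitrarily among effective duplicates —
so the planted-signal benchmark removes near-duplicates (|r| > 0.9
with a driver) before fitting.

## Synthetic MET generator

The generator's defaults describe a desk-scale maize trial network:
40 inbred parents genotyped at 400 markers in 10 chromosomes with block
LD (shared latent draw per 10-marker block plus 15% mutation), target
mean MAF 0.3, configurable missingness/heterozygosity/multi-allelic
fractions; 80 single-cross hybrids (dosage = parental mean); 4 sites on
a north–south gradient × 4 years; two replicates; each hybrid tested in
half the years (unbalanced allocation is what makes genotype-disjoint
CV00 training sets possible at all). Weather is a site-specific
seasonal sinusoid with AR(1) daily anomalies, Markov-chain rainfall
occurrence with gamma amounts, bounded RH/wind noise and a clear-sky
solar profile modulated by cloudiness; the 30-minute expansion is
exactly consistent with the daily skeleton, so the sub-daily → daily
aggregation path can be validated against it. Injectable faults (stuck
sensor, record gaps, out-of-range spikes) exercise the QC rules.
Silking is the first day cumulative growing degrees from planting reach
a per-hybrid thermal requirement (mean 900 GDD, SD 60 — about 5 days of
mid-season spread); the 220-day season leaves room for the grain-filling
window at the coolest site.

Phenotypes follow the additive variance-component structure exactly:
default components (trait units Mg/ha, μ = 9.5) are σ²_E = 2.0,
σ²_g = 0.5, σ²_w = 0.5, σ²_gw = 0.3, σ²_gE = 0.3, σ²_rep = 0.05,
σ²_ε = 1.0 — an environment-dominated decomposition typical of yield
trials. A replicate effect is included so the stage-1 model has
something to estimate. Each realized term is rescaled to hit its
component exactly (recorded in the truth record), g is a linear
combination of marker dosages, w a regression on the standardized W,
gw a sparse marker-by-covariate interaction (10% nonzero coefficients
per covariate, matching the G∘Ω covariance in expectation), and gE an
independent N(0, G) draw per environment. Optional outlier plots are
shifted by a configurable multiple of the residual SD.

What the generator does *not* emulate: spatial field trend, dominance
or epistatic genetic effects, multi-trait correlations, irrigation
management beyond a fixed schedule, crop-growth-model physiology, and
real weather's extremes and missingness patterns. Passing tests
therefore demonstrate correctness of the machinery and recoverability
under the stated model, not performance on real G2F-style data.

## Benchmark problem sizes

The packaged experiments are sized for a single CPU: variance-component
recovery uses ~1,500 hybrid-in-environment observations (84 hybrids,
6 sites × 6 years, half-year allocation) with 4,000-iteration chains,
averaged over 5 seeds in the test suite (3 in the acceptance script).
The covariate-advantage experiment makes genotype-by-covariate
interaction the dominant component (σ²_gw = 1.5 against E 1.0, g 0.3,
w 0.3, gE 0.1, ε 0.8): the reaction-norm comparison (MCMC-bound) runs
at ~360 observations with 1,500-iteration chains, the GBDT comparison
(cheap fits) at ~1,500 observations with 30 PCs and a deep,
feature-subsampled configuration of the kind tuning selects on
interaction-dominated responses. Ten replicate seeds in the test suite,
six in the script.

## Known limitations

- σ²_w posterior means are inflated at desk scale (see above); compare
  ranks, not point values, for weakly identified components.
- The GBDT covariate advantage in CV00 is small relative to its
  seed-to-seed variance at these sample sizes; it is reported as a win
  fraction plus a mean gain rather than a single number.
- No spatial adjustment in stage 1; heterogeneous error variances per
  replicate are not modeled.
- Kriging-based gap filling, dominance kernels, nonlinear (Gaussian /
  arc-cosine) kernels and multivariate GBLUP are out of scope.
- The orchestrator relies on seeded determinism rather than persistent
  stage caching; rerunning a stage reproduces identical artifacts, but
  nothing is memoized across processes.
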