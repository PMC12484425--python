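# Methods notes

## The model and its assumptions

`hurdlevp` fits a two-part ("hurdle") multivariate model to community
count data aggregated to trap-years. The occurrence part is a
multivariate probit: a latent Gaussian score per unit and species whose
sign determines presence, with the residual variance fixed at 1 for
identifiability. The abundance part models the natural log of counts,
restricted to units where the species was recorded; it assumes counts
conditional on presence are lognormal with a per-species residual SD
σ_j. The two parts share no latent state and are fitted independently —
presence carries no information about the abundance residual and vice
versa, which is exactly the hurdle factorisation.

Species are coupled in two ways:

1. **Trait-structured coefficient prior.** Column j of the coefficient
   matrix follows `B_·j ~ N(Γ t_j, Ω)` with `t_j` the species' trait
   vector (intercept, standardized wing span, five host-group
   indicators, reference level = herbaceous feeders). Γ carries
   independent N(0, τ²_Γ) entries (τ_Γ = 2 by default) and Ω an
   inverse-Wishart prior (ν = p + 3, Ψ = 0.5 I). Rare species therefore
   borrow strength from functionally similar common species.
2. **Latent-factor random effects.** Each random level (site, year,
   zone; 2/1/1 factors by default) contributes `η_ℓ' λ_j` with
   standard-normal factor scores and species-specific loadings. The
   per-species variance of a level is Σ_h λ²_h j, invariant to factor
   rotation, which is the only functional of the loadings the analysis
   consumes. Loadings have a geometric variance-decay prior (variance
   halving per successive factor, first-factor SD 1): a deliberate,
   simpler stand-in for adaptive shrinkage processes with the same
   variance-partitioning semantics and verifiable conjugate updates.

All conditionals are conjugate; the Gibbs cycle is truncated-normal
latents (PA only) → coefficient columns → (Γ, Ω) → factor scores and
loadings per level → residual variances (AB only). Defaults: 2 chains ×
2000 iterations, 50% burn-in, thinning 2. Convergence is monitored by
split-R̂ on a random 5% of coefficient traces and logged, not enforced;
on the package's reference problems the slowest traces are
trait-hyperparameter-coupled coefficients and sit near 1.1–1.4 at the
default length, while posterior means and variance shares are stable
(the recovery checks pass with wide margins). Latent probit scores are
clipped at |z| = 40 (≈ the double-precision tail limit); clip events are
counted and logged.

### Degenerate inputs and numerical choices

* Species with fewer than 5 positive units trigger a warning in the AB
  part (wide posteriors expected); all-zero species are legal in the PA
  part and shift the intercept posterior negative.
* AUC uses rank-based Mann–Whitney concordance with 0.5 credit for
  ties; metrics undefined for single-class species propagate as NaN,
  never as 0.
* Undefined clumpiness (forest-free or all-forest buffer) propagates as
  NaN and is excluded from design standardization with a warning; the
  study generator imputes the metric's limit value (0 / 1) instead so
  every unit stays usable.
* The zero-variance guard in design construction names the offending
  column; prediction-grid matrices always reuse frozen training
  standardization statistics (no leakage of the grid distribution into
  the fit, and construction is idempotent given the stats).

## Covariates

Habitat: proportions of broadleaf, coniferous, mixed forest and
semi-natural/herbaceous cover in a square 500 m × 500 m buffer (25 px at
20 m resolution); clumpiness of the merged forest mask (rook adjacency,
double-count convention, in [−1, 1]); marginal entropy of the full
8-class composition in bits (base configurable). Climate: growing
degree-days above 5 °C over the sampling season (1 Apr–15 Oct), chilling
degree-days below 5 °C over the preceding winter (16 Oct–31 Mar,
reported as a positive magnitude so larger = colder), mean winter snow
depth (cm) and cumulative season precipitation (mm). Land-cover epochs
are assigned to observation years by the nearest-epoch rule with ties to
the earlier epoch. Quadratic terms are added for the four proportions
and the four climate covariates but not for clumpiness/entropy (no
biologically plausible optimum for fragmentation) or effort.

## Variance partitioning

Fixed-effect components use the empirical covariance C of design columns
over the prediction grid: `V_g = Σ_{k∈g} B_kj (C B_·j)_k`. This is the
unique symmetric split of cross-group covariance that is exactly
additive to Var(x'B_·j); under correlated covariates an individual V_g
can be negative, and such values are reported raw with a flag rather
than truncated (truncation would silently destroy the additivity the
acceptance checks rely on). Effort is pinned to a constant over the grid
so it contributes zero variance. Random-effect components are the
per-species sums of squared loadings, cell-invariant by construction;
in the conditional partition they are therefore assigned wholly to the
within-context side, while the fixed predictor splits exactly by the law
of total variance (cell-count weights, population variances). Grid
cell-years are pooled across all years by default, so climate's temporal
variation contributes to its share; a per-year variant is a caller-side
restriction of the grid.

Environmental contexts come from k-means (k = 4, 10 restarts, fixed
seed) on the full 8-category land-cover composition — not only the four
model covariates, so water- and wetland-dominated profiles can emerge.
Profiles are named after any category with mean proportion > 0.5, else
"heterogeneous". Functional contexts pool the share draws of species in
a trait group (host-plant group or wing-span bin); the pooled
(habitat, climate) pairs are the object of interest, summarised by
marginal quantiles.

## Scenarios and diversity

The habitat-only scenario freezes each cell's climate covariates at its
mean over the first five years; the climate-only scenario freezes
habitat covariates at their first-epoch values. Richness is the expected
richness Σ_j p_j (smooth, no thresholding); evenness is Hill–Simpson
(inverse Simpson over S) computed on posterior-mean unconditional
expected abundances p_j·exp(μ_j + σ_j²/2) with S = number of modelled
species (all species have positive expected abundance under the
lognormal part, so S is well defined; a draw-wise variant is available
via the prediction API). Random effects at unobserved grid cells are set
to zero — the maps are posterior-expected surfaces, not stochastic
realisations — while observed levels (years, zones) use their posterior
factor scores. Per-cell trends are OLS slopes of metric on year;
residuals are standardised by the cell's temporal mean (relative
variability; per-cell SD standardisation would be identically 1
everywhere, raw residual variance is available via `standardize="none"`).

## Synthetic data generator

The generator emulates a national light-trap monitoring design at desk
scale — the default study is 15 species at 80 sites over 12 years with a
25 × 20 prediction grid — preserving the structural features the method
must cope with:

* **Landscape**: 8 spatially clustered land-cover classes from
  quantile-slicing a smoothed Gaussian field plus an independent
  water/wetland field; epochs every 6 years differ in at most a set
  fraction of pixels, each copying a random neighbour (spatially
  coherent churn). An optional directional-conversion knob sends a
  fraction of changed pixels to a fixed target class, producing genuine
  land-use trends.
* **Climate**: deterministic seasonal curves shifted by a latitudinal
  gradient (0.8 °C per degree), a warming trend (0.04 °C/yr) and iid
  cell-year deviations (SD 0.8 °C). Summer and winter deviate
  independently (winters 1.5× more variable) so thermal-sum and
  chilling covariates are informative rather than collinear; snow
  couples partially to winter cold with its own noise.
* **Sampling design**: the probability that a grid cell hosts a trap
  halves per latitude band, reproducing the southern-biased,
  non-representative design that motivates predictive (rather than
  in-sample) variance partitioning. Zones are 4 equal latitude bands.
  Effort varies as 80–180 trap-days per trap-year.
* **Parameters**: drawn from the model's own prior family so the fitted
  model is well-specified. Block effect scales (habitat 0.45, climate
  0.30 on the probit scale) make habitat the typically dominant driver.
  The intercept row of Γ is chosen so the trait-predicted predictor at
  the average sampled unit is exactly the calibration target (0 for PA
  → prevalences centred near 0.5; 3.2 for AB → tens of individuals per
  positive trap-year, the realistic order of magnitude for light-trap
  catches) — without this, the non-zero means of quadratic columns
  would push whole species to degenerate prevalences. Abundance-part
  effects are shrunk by 0.55 relative to occurrence so simulated counts
  stay realistic.
* **Counts**: rounded lognormal draws with floor 1 given presence. The
  rounding makes the fitted lognormal very slightly misspecified at
  small counts; at the calibrated abundance scale the effect is
  negligible (coefficient coverage sits at its nominal level).

What the generator does **not** emulate: real geography and legends,
spatial autocorrelation in the probit residual, observation error in
climate, missing trap-years, zero-inflation beyond the hurdle, or
phylogenetic structure. Passing tests therefore demonstrate correctness
of the machinery and recoverability under the model's own assumptions —
not robustness to the many ways real monitoring data violate them.

## Scales used by the checks

The recovery checks fit the reference study (15 species × 960 trap-years,
2 × 2000 iterations per part) and partition variance over the 500-cell ×
12-year grid; the single-driver scenario experiment uses 20 replicates
of a 120-cell, 12-year configuration with habitat-driven trends
(directional conversion, no warming) and climate-driven interannual
noise, predicting from the generator's true parameters. These sizes were
chosen as the smallest that keep all structural features and stable
test statistics. Rank-based share recovery (Spearman across 15 species)
is the noisiest quantity: when a draw of true parameters happens to give
species tightly clustered habitat shares, ranks carry little signal and
the correlation can dip even though absolute share errors remain small.

## Open design choices made here

* Square (not circular) 25 ha buffers; clumpiness on the merged
  three-class forest mask; entropy base 2 — all configurable.
* "Prevalence higher than 10%" read as a strict inequality over
  trap-years; the boundary case has measure zero on synthetic data.
* Wing spans between 0 and the first bin edge (absent in the trait
  tables the binning was designed for) go to the nearest bin with a
  warning.
* The predictive-power protocol is a site-stratified random holdout
  (each site keeps training years, so its random effect stays partially
  pooled); no cross-validation variants.
* Chilling degree-days reported as a positive magnitude (monotone:
  larger = colder winter).
* Pipeline stages persist everything as CSV/YAML/NetCDF (scipy NetCDF3
  backend) and plain TIFF + legend CSV for rasters; runs are
  deterministic given config seeds, and `resume` restarts from the
  first stage whose marker output is missing.
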