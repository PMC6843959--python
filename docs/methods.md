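# Methods

## The model

`coastpop` implements dasymetric population disaggregation: census counts
known only for coarse administrative units (counties) are redistributed to a
fine regular grid using ancillary covariates as allocation weights, while
the unit totals are preserved exactly. The modelling assumption is that the
natural logarithm of population density is predictable from geographic
covariates: nighttime light radiance, annual-maximum NDVI, elevation, slope,
a binary settlement footprint, and a composite POI density. A regression is
trained at the county level — zonal-mean covariates against
`y = ln(census_pop / area_km²)` — and then applied cell-wise; the per-cell
prediction becomes the weight `W_grid` in

    POP_grid = POP_county · W_grid / W_county ,   W_county = Σ W over the county.

Because the redistribution is a ratio, the population grid is invariant to
any positive rescaling of the weight surface, and conservation of county
totals holds by construction (verified to < 1e-9 relative in the tests, and
in practice at machine precision).

### Weight modes

Two weight modes are shipped because the field is genuinely ambiguous about
whether a log-scale prediction should be back-transformed before Eq.-style
weighting. `exp` (the default) exponentiates the ln-density prediction, so
weights live on the density scale — standard dasymetric practice, and the
interpretation under which the model is a density model. `raw` uses the
ln-scale predictions directly as weights (clipped at zero); published
weight-layer ranges that coincide numerically with ln-prediction ranges
indicate this usage in practice. Both modes conserve mass exactly; `exp`
concentrates population more strongly. The choice is a config switch
(`weight_mode`) and both are exercised by the test suite.

### The two regression engines

* **Bagged regression-tree ensemble** (`regressor="rf"`): an explicit
  bagging loop over CART regression trees with per-split feature
  subsampling, mtry = ⌈p/3⌉ = 2 of the 6 covariates, 500 trees, fully grown
  (min_samples_leaf = 1 — with bootstrap resampling this is the classic
  regression-forest configuration; on a 200-row noiseless linear benchmark
  it reaches OOB R² ≈ 0.92, where leaf size 5 plateaus near 0.88). Roughly
  one third of the rows are out of bag for each tree, giving the internal
  OOB error estimate, and %IncMSE permutation importance is computed by
  re-evaluating the OOB error with one feature column permuted (mean over
  `n_repeats` = 10 permutations). Ensemble predictions are averages of
  training targets and therefore *cannot leave the training-target range*.
* **M5-style model tree** (`regressor="m5"`, alias `"cubist"`): greedy
  binary splits maximising the standard-deviation reduction
  SDR = sd(S) − Σ |Sᵢ|/|S|·sd(Sᵢ), stopping at `min_leaf` = 4 rows per side
  or when a node's sd falls below 5 % of the root sd; least-squares linear
  models at every node over the features tested in that node's subtree;
  bottom-up pruning comparing pessimistic error estimates
  err·(n+ν)/(n−ν) (ν = model parameters, err = mean absolute residual);
  optional leaf-to-root smoothing p′ = (n·p + k·q)/(n + k) with k = 15.
  Rules are exported as path-condition conjunctions with their leaf models,
  and importance is the Cubist-style VarImp (%): the mean of the share of
  training rows whose covering rule tests a feature in its conditions and
  the share whose leaf model uses it. Linear leaves *extrapolate* beyond
  the training-target range — the substantive contrast with the ensemble:
  on covariate combinations richer than any training county the model tree
  can predict denser-than-observed cells while the ensemble saturates.
  Committees and instance-based correction (features of the commercial
  Cubist) are deliberately out of scope. Degenerate inputs: a constant
  target yields a single constant rule; if the stopping rule forbids any
  split (e.g. `min_leaf` ≥ n) the tree is one global linear rule.

Ties in the SDR search are broken by lowest feature index, then lowest
threshold, making both engines deterministic given the seed and row order.

## Covariate engineering

* **NDVI max composite**: cell-wise maximum over the 36 ten-day images,
  ignoring nodata (all-nodata cells stay nodata) — the standard device for
  suppressing clouds and seasonal lows.
* **POI kernel densities**: ArcGIS-style planar KDE with the quartic
  (biweight) kernel, bandwidth 2000 m, evaluated at cell centres in
  points/m², no boundary correction. The kernel function is the quartic
  because that is what the planar KDE tools of the major GIS packages use;
  bandwidth selection (a search over 500–8000 m on real data) is out of
  scope and the bandwidth is a config parameter.
* **POI composite**: the 20 per-category density layers are standardised
  (PCA on the correlation matrix — the raw layers differ in scale by three
  orders of magnitude, so covariance-scale PCA would be dominated by the
  few largest categories) and reduced to the first principal component,
  sign-oriented to correlate positively with mean density. The explained
  variance fraction is reported in the stack metadata, never asserted: it
  is data-dependent (≈ 49 % on the default synthetic scene, where many
  rare categories are near-empty Poisson samples).
* Elevation and slope: slope by Horn's 3×3 method (the common GIS default)
  with edge-replicated neighbourhoods; nodata propagates to any cell whose
  neighbourhood touches it.

Compositing is performed before any resampling when both are needed; on the
synthetic scenes every layer is already on the common grid. Reprojection is
out of scope throughout: the CRS is an opaque tag checked for equality,
mirroring a workflow already in a planar equal-area projection. The raster
distance-to-coast operator (exact Euclidean distance transform on cell
centres) approximates a vector coastline buffer on the raster.

## The synthetic landscape generator

`generate_scene` builds a seeded world with the statistical structure the
method assumes, so the full pipeline is testable without any data download:

1. sea occupies the left ~18 % of the domain behind a smoothly wavy
   coastline; elevation is a 1.5 m/km inland ramp plus smooth roughness
   (sd 4 m), clipped at sea level;
2. settlements are Gaussian intensity blobs (σ 1–6 km) biased toward low
   elevation; the footprint layer thresholds this intensity, nighttime
   light is the intensity convolved with a 1000 m blooming kernel, NDVI is
   a seasonal sinusoid damped by built fraction with observation noise;
3. the true log density is a linear combination of standardised latent
   covariates (coefficients 0.8 ntl, −0.5 ndvi, −0.6 elevation, −0.3 slope,
   0.7 footprint, 0.8 amenity) plus a settlement term (1.2), plus a smooth
   *unobserved heterogeneity* field (sd 0.5 score units, correlation length
   ≈ 1.2 km) standing in for the spatial nonstationarity of real censuses
   that no covariate can explain. Urban-core fields are log-compressed
   before standardisation (radiance-like fields are log-normal-ish; an
   uncompressed z-score would blow the log density up by tens of ln units
   in the cores). The systematic score is rescaled to a cell-level sd of
   1.3 ln units — aggregated to counties this reproduces the roughly
   7-ln-unit county range reported for real coastal census data — and
   iid N(0, noise_sd = 0.3) cell noise is added on the ln scale;
4. the surface is exponentiated and scaled to 5,000,000 people; POIs are an
   inhomogeneous Poisson draw per category with intensity
   rate_k × population, the per-capita rates taken from the published
   category counts of a 2.58-million-POI national inventory divided by the
   national population (so category sizes span 311 to 591,372);
5. admin units are nested Voronoi partitions on seeded cells — 4 provinces,
   60 counties, 12 townships per county (matching the ≈13 townships per
   county of the real two-level census design, scaled to a 51.2 km × 51.2 km
   domain at 512×512 cells, which keeps every stage under a few seconds on
   one CPU) — and census counts are exact zonal sums of the true surface
   at every level.

Each generation stage draws from its own seeded substream, so varying one
knob (say `noise_sd`) perturbs only its own field while terrain, admin
partition and POI sampling stay paired across configurations — common
random numbers for clean ablation and sensitivity experiments.

**What the generator does and does not emulate.** It reproduces the
structural features the method relies on: settlement-concentrated
population, covariates that are distorted proxies of the drivers, POIs that
track population, nested units with exact censuses, and unexplainable
spatial heterogeneity. It does not emulate real coastline geometry, the
semantics of POI categories, registration errors between layers, census
undercount, or non-log-linear density regimes. Passing tests therefore
demonstrate correctness and the expected *qualitative* behaviours
(conservation, the POI ablation gain, the dense-underestimate /
sparse-overestimate smoothing bias, the interpolation/extrapolation
contrast); they do not certify error magnitudes on real data, which are
dominated by the very distortions the generator idealises.

## Validation

Township censuses are held in reserve and compared with zonal sums of the
predicted grid: MAE, RMSE, %RMSE (RMSE over mean census), MRE (%) — the
mean *absolute* relative error over positive-census units, since the usual
verbal definition leaves the sign convention open — and R² as the squared
Pearson correlation of log10 densities over units where both census and
prediction are positive. Excluded units (zero census, or zero prediction in
the log-log R²) are counted and reported rather than silently dropped. The
stratified report cuts units at the 20th/80th census-density percentiles
(ties to the lower stratum) and reports per-stratum R² and mean signed
log10 error; on default scenes the characteristic dasymetric smoothing bias
appears as a positive mean in the bottom stratum and a negative mean in the
top stratum. The POI ablation re-runs the pipeline with the composite POI
layer replaced by zeros — rather than dropping the column — so a scene
without POIs yields two bitwise-identical runs, and on informative scenes
the with-POI run has lower township MAE essentially always.

## LECZ exposure

The zone is `land ∧ elevation < 10 m ∧ distance-to-coast < 100 km`, both
inequalities strict following the zone's verbal definition (boundary cells
at exactly 10 m are excluded; both thresholds are parameters). The optional
`require_coast_connectivity` flag additionally keeps only 8-connected mask
components touching the coast — the "contiguous area along the coast"
reading — and is off by default to match the plain three-step overlay
(buffer ∩ low-elevation) that practice uses. Exposure tables report
per-region exposed population, total, and percentage (undefined, not zero,
for empty regions), plus a global row. DEM error propagation into exposure
is a known limitation and is not modelled.

## Numerical choices and degenerate inputs

* Nearest-neighbour resampling resolves ties toward the lower index
  (identical to a first-match argmin over source centres); bilinear
  resampling clamps to edge centres (flat extrapolation) and propagates
  nodata from any contributing corner.
* Zonal statistics flag labels with zero valid cells as missing (NaN), not
  0; training-table construction drops such units (and zero-population
  units) with a log entry and reports the counts.
* A census unit whose weights sum to zero falls back to uniform allocation
  over its valid cells (logged); a unit with census but no valid cells is
  an error.
* All-zero POI layers (ablation, or scenes without POIs) pass through the
  stack as a constant feature: trees never split on it, so the ablated
  pipeline is exactly the five-variable model.
* GeoTIFF I/O round-trips values, grid geometry and the nodata sentinel
  bit-exactly (nodata is serialised with 17 significant digits).

## Default problem sizes

The default scene is 512×512 cells at 100 m. The full pipeline (scene,
KDE + PCA, both engines, redistribution, validation, exposure) runs in
about 15 s on one CPU; the test suite, which includes twenty-scene
conservation sweeps and ten-seed ablation and bias studies, completes in a
few minutes. Scaled-down scenes (64–128 px) are used where a test needs
many repetitions; they share the default study conditions except for domain
size, unit counts and total population, which scale with area.

## Known limitations

* The M5 engine is a single model tree; Cubist committees and
  nearest-neighbour correction would likely improve its accuracy.
* Only two admin levels participate in modelling (train on counties,
  validate on townships); hierarchical multi-level redistribution is out of
  scope.
* KDE bandwidth is fixed, not searched; PCA keeps exactly one component.
* The LECZ mask is raster-based; vector coastline buffering and
  hydrological connectivity are not implemented.
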