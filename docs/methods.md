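# Methods

## Overview

`nicheshift` implements an ensemble species-distribution-modelling
protocol — occurrence preparation, predictor selection, spatially blocked
cross-validation, a four-family ensemble with AUC-weighted projection —
together with the two analyses that consume its projections: national
aggregation of richness change against socioeconomic covariates, and
per-border accounting of transboundary ranges, range shifts and barrier
conflicts. A synthetic-world generator supplies every input with known
ground truth, so the pipeline's statistical behaviour is validated by
recovery rather than asserted.

## The synthetic world

**Grid.** An abstract equal-area grid (`GridSpec`) with uniform
`cell_area`; all areas downstream are cell counts × `cell_area`. Rows
carry a pseudo-latitude running from 70° (row 0, "north") to 0°
(equator), a single-hemisphere abstraction that gives monotone
latitudinal gradients for both climate and national covariates.

**Climate.** Eight candidate bioclimatic variables, four per class
(temperature: annual mean, seasonality, warmest-month max, coldest-month
min; precipitation: annual mean, seasonality, wettest-month,
driest-month). Each layer is a deterministic latitudinal gradient plus
spatially autocorrelated noise (Gaussian-filtered white noise, filter
radius `autocorr_range` in cells, default 3 — fields correlated over a
few cells, as coarse-grained climate is). The mean/extreme pairs within
each class are constructed strongly collinear (|r| ≈ 0.95–0.99), as their
real counterparts are, so the collinearity filter has realistic work;
cross-class correlations sit near or below the 0.7 threshold and vary
with the seed. Futures add per-scenario shifts (default warming ladder
1.0 / 1.8 / 2.2 / 3.7 °C for the four scenarios, with precipitation
shifts proportional to warming) plus a per-pseudo-GCM offset and smooth
anomaly field scaled by `gcm_spread` (default 0.1). Seasonality and
precipitation layers are clipped at zero. A zero delta specification
reproduces the current layers bit-for-bit.

**Regions.** Realms are contiguous latitudinal bands. Ecoregions grow
from seeded nuclei within each realm (nearest-seed assignment), with ~2
nuclei per ecoregion label on average so ecoregions recur as disjoint
patches; fragments are their 4-connected components. Countries are a
nearest-seed partition of the whole grid. 4-connectivity defines both
fragment contiguity and country adjacency; the border graph has an edge
wherever ≥ 1 adjacent cell pair spans two countries, and a seeded random
`barrier_fraction` (default 0.15) of borders is flagged fortified.
Maritime/disjunct adjacency is out of scope: only land-contiguous
adjacency produces borders.

**Species.** Suitability is a product of Gaussian response curves over
1–2 "true" variables drawn from the five niche-defining predictors;
optima sit in the interior quantiles (25–75%) of the variable's current
distribution and breadths are 0.6–1.4 spatial standard deviations by
default. The home realm is the realm of the most suitable cell; the
occupancy cutoff is the suitability quantile matching a prevalence drawn
from `prevalence_range` (default 10–40% of home-realm cells). Presences
are exactly the super-cutoff realm cells — no label noise — so recovery
tests can compare against an exact truth. Taxon group (bird/mammal ~50:50),
a flying tag (all birds plus ~10% of mammals, the "bat" path) and a 20%
threatened tag emulate the attribute filters of the real analyses.

**Covariates.** Six governance indicators share a country-latitude signal
(`gradient_strength`, default 1) plus indicator-specific noise, clipped
to the standardized [−2.5, 2.5] range; GDP and CO₂ per capita are
log-normal with latitude-linked location. `gradient_strength = 0` is the
null configuration used by coverage tests.

What the generator does **not** emulate: real-Earth geometry, dispersal
limitation beyond the realm constraint, biotic interactions, label noise
in ranges, non-climate range determinants, and the spatial sampling
biases of real atlases. Passing recovery tests therefore demonstrate
that the pipeline's machinery is correct and well calibrated under its
own assumptions, not that any real-world projection is accurate.

## Occurrence preparation

Range polygons (real-data mode) are filtered to extant (presence code
1–2), native (origin 1), breeding/resident (seasonality 1–2) sub-polygons
and rasterized: a cell is presence at ≥ 10% polygon overlap, computed by
exact shapely intersection. Synthetic species bypass rasterization (they
are generated on-grid). Species with fewer than 10 presence cells are
excluded as range-restricted. Each retained species receives 1,000
pseudoabsence cells drawn uniformly *without replacement* from the
realms in which it occurs, *excluding* its presence cells — contaminated
absences would bias every downstream AUC and threshold; if fewer cells
are eligible, all are taken and the shortfall logged; zero eligible
cells is a hard error. Sampling draws from a canonically ordered cell
list, making it invariant to enumeration order and reproducible by seed.

## Predictor selection

All subsets of 3–8 of the eight candidates are enumerated (219); subsets
lacking either class are discarded (10); subsets containing a pair with
|Pearson r| > 0.7 — strictly greater, computed over all grid cells — are
discarded. Absolute correlation is used because strong negative
collinearity destabilizes coefficients just as positive does. A constant
variable has undefined correlation and is treated as a violation.
Survivors are ranked by fitting the additive-spline model per test
species and per subset, ordering by AIC (penalized log-likelihood plus
twice the effective degrees of freedom), marking the best ⌈n/4⌉
subsets, and tallying top-quartile appearances across species; the
winner has the highest tally, with ties broken by smaller subset then
lexicographic order. The default test-species count is 20 in synthetic
runs; production-scale runs would use a couple of hundred per taxon
group, and the count is exposed in config.

## Spatial blocking

Fragments (noncontiguous ecoregion portions) are the sampling units.
They are grouped into 10 global blocks — shared by all species — by a
greedy balancing pass: fragments sorted by area descending (seeded
shuffle breaks exact ties); the 10 largest seed one block each, which
guarantees 10 non-empty blocks; each remaining fragment joins the block
minimizing a weighted score = CV of block areas + mean over variables of
the between-block SD of area-weighted climate means (per-variable
standardized). Both weights default to 1 and are exposed in config since
no canonical weighting exists. After assignment each block's climate
envelope is checked to cover ≥ 80% of the global min–max per variable;
shortfalls are logged, not fatal. The greedy result is validated in
tests against the best of 1,000 random assignments and a ≤ 1.5 block-area
max/min ratio on 100+-fragment worlds. Exact optimal partitioning is
NP-hard and out of scope.

## The ensemble

Per species, folds are the intersections of its occurrence rows with the
10 blocks; a fold is viable when training and held-out parts each
contain both classes. Family rules:

* **GLM.** Per-variable orthogonal polynomial bases (QR-orthonormalized
  powers of the standardized variable, decoupling degree terms across
  the 243 refits). Every degree assignment in {1,2,3}⁵ is scored by mean
  held-out AUC across folds (a formulation failing in > 50% of folds is
  discarded); the argmax is refit per fold. Fits use iteratively
  reweighted least squares with a weak ridge (λ = 1) — virtual-species
  tables are often perfectly separable and the ridge keeps estimates
  finite without materially changing ranking.
* **GAM.** Additive logistic model on per-variable B-spline bases
  (5 knots, cubic) with a second-difference (P-spline) roughness penalty,
  weight 1 by default, fitted by penalized IRLS. Penalizing curvature
  rather than coefficient size preserves monotone trends near the data
  boundary. Its AIC (−2·loglik + 2·edf, edf = trace of the influence
  matrix) is the criterion used by predictor selection.
* **Random forest.** `mtry` grid {1,2,3}; per (mtry, fold) the forest is
  grown warm-start from the initial tree count in fixed steps, tracking
  mean held-out AUC, and stops at the first step whose relative gain is
  < 1% — the final count is that last tested size. The (mtry, count)
  with the best mean AUC keeps its per-fold forests.
* **Boosted trees.** Fixed shrinkage and tree count; interaction depth
  from {1,2,3,4} minimizing summed held-out binomial deviance, per-fold
  fits reused.

Each surviving fit carries a held-out AUC and a threshold maximizing
sensitivity + specificity, computed **on the held-out block** — the only
data not used in fitting. The threshold objective is evaluated in exact
integer arithmetic so mathematically tied candidates tie and the lowest
optimal threshold (favouring sensitivity) is returned.

**Projection.** Every model scores every cell of the species' domain
(its occupied realms), binarized by its own threshold; the occupancy
fraction is the AUC-weighted mean of the binary layers and the ensemble
map is fraction ≥ 0.5 (the 0.5 cutoff is a package choice). Future projections pool the 40
fits over the three pseudo-GCM grids of one scenario — 120 members.
Failed folds renormalize the weights; fewer than 20 surviving members
flags the species unreliable.

**Hyperparameter profiles.** `EnsembleConfig()` defaults to the
protocol's full-scale tuning rules (RF 1,000 + 500-step trees; BRT shrinkage 0.001
with 5,000 trees). `EnsembleConfig.fast()` is the desk-scale profile
used by the simulation studies and the demo configs — RF 100 + 50-step
trees, BRT 300 trees at shrinkage 0.05 — sized for occurrence tables of
a few hundred to ~2,000 rows, where held-out AUC saturates far below
the production tree counts. All simulation results in the test suite
and acceptance script use this profile; the defaults are asserted
separately.

## National aggregation

Richness maps sum ensemble binary layers per cell; percentage change is
100·(future − current)/current with zero-current cells undefined and
excluded from national means (countries with no defined cells are
omitted with a log line). National means are unweighted over defined
cells. The covariate models are univariate Gaussian GLMs (one per
covariate, mirroring separate-panel analyses) of mean percentage change
on governance score, log GDP per capita or log CO₂ per capita — the
monetary/emissions covariates are natural-log transformed for their
right skew. At least 10 countries are required.

## Transboundary accounting

"Current" occupancy is always the observed range raster, not the
modelled current niche ("not currently known to occur" reads literally);
cells are area-proportional, so all fractions are cell-count ratios.
A species bisects a border when it occurs on both sides; it shifts
across a border when exactly one side is currently occupied and the
other gains ≥ 1 projected future cell — counted once per species per
border, in either direction. Future cells gained in countries not
graph-adjacent to any currently occupied country are recorded as
unattributed jumps, not credited to a border. Normalized statistics
divide by the distinct species richness of the two countries combined.
The barrier analysis restricts to nonflying mammals and to
barrier-flagged borders: blocked species are those whose shift condition
holds on at least one fortified border. The default scenario for border
analyses is the high-emissions analogue, with the moderate scenario as
the documented alternative.

## Pipeline and reproducibility

Stages (`world → prep → select → block → ensemble → national → borders`)
chain through plain CSV/JSON artifacts; the ensemble stage both fits and
writes projections because fitted models live only in memory, and the
CLI's `project` subcommand aliases it. Per-stage seeds derive from the
global seed and stage name (CRC32), so any stage reruns independently
and byte-identically. Unknown config keys are rejected. Every stage
writes a provenance record (config hash, seed, input/output digests,
counts). Raster-like artifacts are cell-indexed CSV; the abstract grid
makes richer geospatial containers unnecessary.

## Numerical choices and degenerate inputs

* AUC is rank-based with ties counted half; single-class inputs raise.
* Logistic fits clip linear predictors at ±30; probabilities at 1e−12.
* Polynomial bases guard near-constant variables with a diagonal bump.
* The rasterization threshold compares with a 1e−12 tolerance so an
  exact 10% overlap counts.
* Empty future niches yield an undefined new-country fraction and a
  "niche lost" flag rather than a zero.

## Problem sizes

Simulation studies use 40×40 grids (1,600 cells), 20 virtual species
with 500+ presences for recovery, 5-species subsets for bookkeeping
assertions, 30-country worlds with 100 replicates for covariate
recovery, and 100+-fragment worlds for blocking balance — sizes at which
every stage's statistical behaviour is already stable and the whole
suite runs on a single CPU.

## Known limitations

* The realm constraint is the only dispersal limit; projections assume
  unlimited within-realm dispersal by 2070.
* Blocking optimizes a heuristic objective; no optimality guarantee.
* The GAM smoothing weight is fixed rather than criterion-selected.
* The synthetic covariate regressions are cross-sectional with no
  spatial error structure, matching the analysis they emulate.
* Border statistics do not localize crossings within a border or model
  barrier permeability.
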