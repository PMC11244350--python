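# Methods

## The model

The core is a presence-background maximum-entropy model.  Let the background
be a finite sample of landscape cells x with feature vector f(x) ∈ [0, 1]^k.
The model is the Gibbs distribution

    q(x) = exp(λ·f(x)) / Z,   Z = Σ_background exp(λ·f(x)),

the maximum-entropy distribution over the background whose feature
expectations match the presence sample, relaxed by an L1 budget.  Fitting
minimizes the convex objective

    J(λ) = −(1/m) Σ_presence λ·f + log Z + Σ_j β_j |λ_j|,

where m is the presence count.  **Training gain** is the improvement in mean
presence log-probability over the uniform distribution,
gain = mean_presence log q − log(1/N_bg); it is 0 for the empty model and is
the quantity compared in jackknife tests.  **Suitability** is reported
through monotone links of q: with H the entropy of the fitted distribution
over the background, cloglog p = 1 − exp(−e^H·q) (the default) and logistic
p = e^H·q / (1 + e^H·q).  For the uniform model both links give the same p
everywhere (cloglog: 1 − e⁻¹ ≈ 0.632), which anchors the scale.

### Features

Variables are scaled to [0, 1] by min/max bounds from the background sample
(clamped at prediction time, so the model never extrapolates features
outside the trained range).  Families: linear z, quadratic z², pairwise
products z_a·z_b, hinge max(0, z−k)/(1−k) and threshold 1{z > k}, with 30
knots per variable at equally spaced background quantiles.  Availability
follows the presence-count heuristic common in this model family: < 10
presences linear only; 10–14 adds quadratic; 15–79 adds hinge; ≥ 80 all
classes.  Constant variables contribute no features and are logged.

### Regularization

β_j = multiplier · b_class · max(σ_j, 10⁻³) / √m, with σ_j the feature's
standard deviation over presences and b_class 0.1 for
linear/quadratic/product, 0.5 for hinge, 1.0 for threshold.  This is a
deliberate simplification of the interpolated tables used by the reference
software in this field; the multiplier (default 1) is the single exposed
tuning knob.  The σ floor keeps features that are constant across presences
from receiving a zero penalty and drifting unboundedly.

### Optimizer

Cyclic coordinate descent.  For coordinate j the step is a soft-thresholded
Newton proposal using the current Gibbs variance of f_j as curvature; the
trial step is accepted only if the true objective decreases, otherwise the
step falls back to the safe quadratic-bound step (f ∈ [0, 1] bounds the
curvature by 1/4, so that step always descends) and then halves.  The
objective is therefore non-increasing by construction — asserted in tests —
and the fit stops when the per-sweep relative decrease falls below `tol`
(default 1e-5, `max_iter` 500 sweeps).  On ≤ 2-feature toys the solution
matches an independent iterative grid-search minimizer to |Δλ| < 1e-3.

### Background

Up to 10,000 valid cells sampled uniformly at random (seeded), with the
presence rows appended to the background — the landscape sample should
contain the places the species was observed.  The raw distribution
normalizes over this combined background; its sum is asserted to 1e-9 after
every fit.

### Diagnostics

* **AUC** — Mann–Whitney form (ties ½), invariant under monotone transforms
  of the scores; both training and held-out presences are scored against the
  training background.  The conventional "excellent" bar of 0.8 is the
  default pass threshold on the evaluation report.
* **Contribution rate** — each accepted coordinate update's unpenalized-gain
  increase is credited to the updated feature's variable (products split
  50/50), negatives floored, normalized to 100.  This attribution is
  path-dependent by construction, as in the reference implementation; the
  sweep order is deterministic so runs reproduce.
* **Permutation importance** — drop in training AUC after shuffling one
  variable's raw values across the combined presence+background sample
  (seeded), floored at 0, normalized to 100.
* **Jackknife** — refits with only / without each variable and reports the
  training gains.
* **Response curves** — sweep one variable across its background range with
  the others held at their presence means.

### Train/test split

Seeded random partition; the train count is floor(0.75·n + 0.5) so that
half-cases round up (374 records → 281/93).  Splitting requires n ≥ 4 and
always leaves at least one record on each side.

## Occurrence preparation

Exact duplicate (species, lon, lat) rows collapse to one; coordinates
outside [−180, 180] × [−90, 90] are dropped with a logged count; an optional
raster mask removes records on nodata cells.  Spatial thinning enforces the
10 km minimum-distance rule as a greedy pass over a seeded random
permutation: a record is retained iff no already-retained record lies
strictly closer than `min_km` (great-circle, authalic sphere, with a
nanometer float tolerance so pairs at exactly the threshold are both
retainable).  The greedy pass guarantees the minimum spacing; the seeded
shuffle makes which cluster member survives random but reproducible, and
thinning is idempotent for a fixed seed.

## Geometry

* **Cell areas** use the spherical band formula
  A = R²·Δλ·(sin φ_top − sin φ_bottom) on the authalic sphere
  R = 6371.0088 km.  Areas are reported to 2 d.p. in 10⁴ km², far coarser
  than sphere-vs-ellipsoid differences; summed over a global grid the
  formula reproduces 4πR² to 1e-6 relative.
* **Distances** between printed coordinates are sharp to ~0.1 km, so
  point-to-point distances use the WGS84 ellipsoid (Vincenty inverse,
  written in-package; validated against an independent geodesic library to
  sub-meter).  Nearly antipodal pairs where the iteration stalls fall back
  to the spherical great-circle with a warning.
* **Compass directions** bucket the initial geodesic bearing into eight 45°
  sectors centered on the cardinal/intercardinal directions.
* **Raster I/O** is Esri ASCII (corner-registered; the `xllcenter` dialect
  is converted on read), written at `%.17g` so write→read round-trips are
  exact.  Nodata is NaN in memory and the sentinel only on disk.  Point
  extraction is containment (nearest-cell), never interpolation — bilinear
  blending would blur nodata boundaries; points on an internal cell edge
  belong to the cell to the north/west (a deterministic tie-break).
  GeoTIFF is not read: no geo-raster library is part of the dependency set,
  and ASCII grids are the interchange format every GIS exports.

## Variable screening

Stage 1 drops variables whose contribution rate in a preliminary all-variable
fit is exactly 0.  Stage 2 computes Pearson correlations between the
remaining variables at the thinned presence points (the environments the
model actually contrasts) and resolves pairs with |r| strictly above the
threshold (default 0.8; |r| = 0.8 is retained) in decreasing |r|, dropping
the member with the lower contribution rate — ties fall to lower permutation
importance, then to the larger bioclim index.  The procedure is deterministic
and the retained set has pairwise |r| ≤ threshold.

Note that presence-point correlations are systematically larger in magnitude
than whole-landscape correlations: presences occupy a narrow, spatially
clustered environmental slice.  On simulated worlds this can push incidental
pairs past 0.8 and prune variables beyond the deliberately constructed
collinear pair; that is correct behaviour for the screening rule, but it is
why the simulator's *constructed* |r| > 0.8 pair is verified against
correlations over a uniform sample of landscape cells.

## Habitat accounting

Classification bins p into non (p ≤ 0.2), low (0.2 < p ≤ 0.4), medium
(0.4 < p ≤ 0.6) and high (p > 0.6) — boundaries belong to the lower class.
The class partition is exhaustive over valid cells, and LSDA + MSDA + HSDA =
TSDA with TSDA + non-suitable = total valid area to 1e-9 km² before
rounding.

For scenario change and centroids, "suitable" means p above the non-suitable
cutoff (default 0.2).  The change matrix cross-tabulates baseline and future
suitable masks into reserved / lost / new / neither, with areas from the
band formula; rates are percentages of the **baseline** total suitable area,
so retention + loss = 100 exactly pre-rounding, and reserved + lost equals
the baseline suitable area.  This shared-denominator convention is the one
that reproduces published loss/increase rates in range-shift tables of this
kind to 2 d.p.; published retention columns can wobble ±0.01 from
independent rounding.

The centroid is the area-weighted mean of suitable-cell centers (binary
mask × cell area); a suitability-weighted variant is available behind a
flag.  Migration tracks report each scenario's centroid with its WGS84
distance and compass sector from the baseline centroid.  Longitude averaging
is planar, appropriate for regional extents away from the antimeridian.

## The virtual-species generator

Each world is built from `n_latent` smooth latent fields (seeded white noise
convolved with a Gaussian kernel of the configured length-scale,
standardized).  Layer i is the loading-matrix combination Σ_t L_it·latent_t
plus independent cell noise, then affinely mapped onto a plausible bioclim
range (temperatures in °C, precipitation in mm), so layer units look right
while the correlation structure is controlled exactly by
corr(i,j) = (LLᵀ)_ij / √((LLᵀ)_ii+σ²)((LLᵀ)_jj+σ²).  True suitability is a
product of response terms — Gaussian exp(−(v−a)²/2b²) or logistic in a
layer's value — each rescaled to [0, 1].  Presences are sampled without
replacement with probability proportional to suitability (not thresholded),
which leaves a meaningful ceiling below 1 on achievable AUC, and jittered
inside their cell.

The **default world** is 200×200 cells over 100–115° E, 20–35° N at 0.075°
(a subtropical study region's scale), 19 layers each with its own primary
latent plus a 0.3 cross-loading (moderate realistic collinearity), and one
engineered collinear pair: bio18/bio19 share a latent with loadings
(1.0, 0.95), giving implied r = 0.948 (empirical 0.945–0.952 across seeds).
The species responds to bio1 alone through a narrow Gaussian niche (optimum
25 °C, breadth 1.2 °C — a warm-climate specialist occupying ~6% of the
region).  The breadth was chosen at design time so the species is strongly
identifiable: the information ceiling (scoring by true suitability) is
AUC ≈ 0.95, leaving room for estimation error above the 0.85 recovery bar.
Default presence count is 374 records.

What the generator does **not** emulate: real marginal distributions of
WorldClim variables, GCM spatial structure, sampling bias fields, or nodata
coastlines.  Passing recovery tests therefore demonstrates correctness of
the estimation machinery under known truth, not performance on real
archives.

Correlation control tightens as smoothing decreases (smoother fields carry
fewer independent cells: at length-scale 8 the empirical correlation of an
independent pair can wander ~0.1 from its target on a 200×200 grid, at
length-scale 1 all pairs sit within 0.05), which is why the ±0.05
correlation-control test runs at length-scale 1.

## Numerical and design choices

* Authalic sphere for areas, WGS84 for point distances (the printed
  distances that anchor the geodesy tests are sharp; areas are printed far
  coarser).
* Exactly-at-threshold conventions follow the printed wording everywhere:
  classification boundaries belong to the lower class, |r| = threshold is
  retained, records exactly `min_km` apart both survive thinning.
* The 75% train count rounds half up (374 → 281/93).
* Degenerate inputs: empty occurrence sets, all-zero contributions,
  no-suitable-cell scenarios and constant variables raise informative
  errors (or, for migration tracks, flag the scenario and continue).
* Problem sizes in the test suite: unit tests run on toy grids and a 60×60
  world; the recovery suite runs ten 200×200 worlds with a
  5,000-cell background, which keeps a full run around two minutes on one
  core while leaving the recovery margins wide.

## Known limitations

* No projection engine, raster resampling or multi-band formats: stacks
  must share one lat/lon grid, and grid mismatch is an error by contract.
* Contribution rates are path-dependent (as in the reference software);
  they are reproducible but not a causal decomposition.
* The L1 path has no cross-validated multiplier selection; a single 75/25
  split is the only built-in evaluation design.
* Vincenty can stall on nearly antipodal pairs; the spherical fallback is
  accurate to ~0.5% there, which is irrelevant at regional scales.
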