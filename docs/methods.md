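# Methods

`ecoreserve` implements a desk-scale workflow for conservation planning of a
forest bird: simulate (or load) an environmental landscape and camera-trap
occurrence records, fit an AUC-weighted ensemble species distribution model
(SDM), map multi-species habitat overlap, and prioritize hexagonal planning
units with a simulated-annealing reserve selector in the style of Marxan.

## 1. Synthetic landscape

Real camera-trap records and reserve geodata for studies of this kind are
rarely deposited, so the package ships a fully documented generator whose
outputs stand in for them.

- **Random fields.** Each continuous layer (elevation `dem`, isothermality
  `bio3`, dry-season precipitation `bio14`, vegetation index `evi`) is a
  Gaussian-filtered white-noise field on the raster grid, rescaled to a
  configured mean/sd. The filter length (`corr_length`, in cells) sets
  spatial autocorrelation; longer lengths give smoother maps (verified via
  Moran's I in the tests). Defaults: 128×128 cells of 30 m; correlation
  lengths 14 (dem), 12 (bio3), 9 (bio14), 6 (evi).
- **Land use.** A 7-class categorical layer obtained by quantile-binning an
  auxiliary random field to configured class fractions (default 0.45, 0.20,
  0.12, 0.08, 0.06, 0.05, 0.04 from least to most disturbed). Random-walk
  polylines add roads and watercourses; road cells are recoded to the most
  disturbed class.
- **True niche.** Occurrence probability is a logistic model on standardized
  covariates: linear terms (default: positive `dem`, negative `slope` and
  `dist_water`), a quadratic optimum in `evi`, a positive effect of distance
  to roads (road avoidance), and aspect preferences through
  eastness/southness. The default coefficients were chosen so the species is
  learnable from a few hundred detections — strong enough that a correctly
  specified model can exceed 0.8 discrimination AUC, which mirrors the kind
  of study this emulates — while leaving realistic residual noise. They are
  generator constants, not quantities fitted to any test.
- **Camera sampling.** Cameras are placed uniformly at random (or
  proportional to an accessibility bias surface) without replacement; each
  camera makes `detections_per_camera` (default 1) Bernoulli(p) trials and a
  detecting camera contributes one presence record at its cell centre.
  `sample_presences` draws camera batches until a requested number of
  presences accumulates. Pseudo-absences are drawn uniformly from valid
  cells that hold no presence, balanced with the presences by default.

What the generator does **not** emulate: observation covariates (effort,
season), spatial clustering of cameras along trails, imperfect geolocation,
species interactions, and temporal dynamics. All structure is stationary
and isotropic.

## 2. Covariate preprocessing

- **Distance rasters** to roads and water use an exact Euclidean distance
  transform.
- **Slope/aspect** come from Horn's 3×3 finite differences on the DEM.
  Aspect is the downslope direction in degrees from north; flat cells have
  undefined aspect (NaN) and contribute zero eastness/southness. Aspect is
  circular, so models receive `eastness = sin(aspect)` and
  `southness = −cos(aspect)` instead of the raw angle.
- **Collinearity screening** happens at the occurrence sample (presences +
  pseudo-absences pooled across species). Stage 1 drops one member of any
  pair with |r| ≥ 0.7 (the member with the larger mean absolute correlation
  against the remaining layers; ties drop the lexicographically later
  name). Stage 2 iteratively drops the layer with the largest variance
  inflation factor until all VIF ≤ 10. Categorical and circular layers are
  exempt. Both cuts are the conventional screening thresholds for SDM
  covariate sets.

## 3. Ensemble SDM

Three base learners are fitted per round:

- `maxent_like`: ℓ2-penalized logistic regression on standardized features
  plus their squares (a minimal emulation of MaxEnt's linear+quadratic
  feature classes),
- `random_forest`: 100 trees,
- `svm`: RBF support-vector machine with Platt-calibrated probabilities.

Evaluation uses stratified 80/20 holdout splits, repeated for 10 rounds
with pseudo-absences re-drawn each round, so every round sees a different
background sample. Per round, each learner is scored by rank AUC on the
held-out 20%; learners with AUC strictly greater than 0.8 enter the
ensemble with weight

  W_i = r_i / Σ_j r_j  (sum over gate-passing learners, r = AUC),

and gated-out learners get weight zero. A round in which no learner passes
is excluded from the ensemble with a warning; the fit fails only if every
round is excluded. The final suitability map is the mean of the per-round
weighted predictions.

Reported metrics (per species, averaged over rounds): AUC, TSS at the
max-TSS threshold, omission rate, proportion correct, and Cohen's kappa.
The max-TSS threshold scans midpoints between sorted unique scores and
takes the lowest maximizer.

**Variable contributions** are permutation importances on the prediction
map: permute one covariate across valid cells (eastness and southness
jointly, reported as `aspect`), recompute the map, take 1 − Pearson r
against the baseline, average over permutations, and normalize shares to
100%. **Response curves** sweep one covariate over its observed range with
all others held at their presence-sample means (mode for land use).

## 4. Habitat overlap

Suitability maps are binarized at a strict threshold (default 0.7:
suitable iff suitability > 0.7). The overlap map counts, per cell, how many
species' suitable areas include it; the class table reports area (km²) by
species count. Class areas partition the union exactly.

## 5. Planning units, cost, and the Marxan dialect

The study area is tessellated with flat-topped hexagons of configured full
area (default 0.1 km² on the demo extent); boundary hexes are clipped.
Adjacency, shared-edge lengths and each unit's exposed outer edge come from
the clipped geometry; vertices are rounded to 10⁻⁶ m, so geometric
identities hold to about that precision. Interior complete hexes always
have six neighbours.

Unit **cost** is a human-disturbance index M = Σ_n f_n·h_n, where f_n is
the unit's area share of disturbance level n and h_n its intensity. The
default scheme maps the 7 land-use classes to levels 1–7 with h_n = n/7
(non-decreasing by construction). Units containing no raster cell centre
receive the mean observed cost with a warning.

Feature **amounts** per unit are suitability-weighted areas
(Σ suitability × cell area over cells whose centre falls in the unit), so
total amount is conserved under aggregation; a threshold mode gives plain
suitable-area accounting instead.

Problems round-trip through the standard four Marxan data files (`pu.dat`,
`spec.dat`, `puvspr.dat`, `bound.dat`), tab-separated with `%.10g`
numbers; outer boundary is encoded as `id1 == id2` rows.

## 6. Reserve selection

The objective is

  O = Σ cost + BLM · boundary + Σ SPF · penalty,

with boundary the exposed perimeter of the selection (outer edges of
selected units plus shared edges whose other side is unselected), and the
penalty for each feature equal to its normalized target shortfall times a
greedy base penalty (the cost + boundary of a greedy cover that meets the
target, the conventional Marxan construction — deterministic and
documented, since published descriptions leave it loose). Defaults follow
the emulated study design: SPF = 16.74, BLM = 2.11, target = 50% of each
feature's total amount.

Annealing uses single-unit flip proposals with Metropolis acceptance,
initial temperature set adaptively to the 90th percentile of |ΔO| over 100
random flips, geometric cooling to 10⁻⁴ of the initial temperature, and a
terminal iterative-improvement pass (remove-then-add to a fixed point).
ΔO is computed incrementally and is tested to match full re-evaluation.
Repeated independent runs (demo: 200; the emulated design uses 1000) give
per-unit selection counts; **key protection areas** are units selected in
strictly more than 90% of runs, optionally filtered to connected components
of at least 2 units (a documented stand-in for "contiguous patches only",
whose in-solver enforcement is unspecified in the emulated design). A
BLM × SPF sensitivity sweep replaces interactive calibration tools.

## 7. Numerical and scale choices

- All rasters are plain-text ESRI ASCII grids and all vectors GeoJSON, so
  the package needs no GDAL stack; coordinates are metric and planar.
- Every stochastic step takes an explicit integer seed; the pipeline
  derives one sub-seed per stage from the master seed (all < 2³¹). Stage
  outputs are content-hashed so unchanged stages are skipped on re-run.
- The demo problem is deliberately scaled down from landscape scale: a
  ~14.7 km² extent, 168 planning units of 0.1 km², 200 annealing runs of
  20 000 iterations. The optimizer itself is validated against exhaustive
  enumeration on problems small enough to enumerate.

## 8. Limitations

- Pseudo-absence-based evaluation upper-bounds true discrimination; AUC
  against background is not AUC against verified absences.
- The `maxent_like` learner is a logistic approximation, not MaxEnt; hinge
  and product features are not implemented.
- Permutation contributions measure map sensitivity, not causal effects,
  and split credit between correlated covariates that survived screening.
- The annealer gives no optimality guarantee beyond the tested regimes;
  selection frequency is an operational irreplaceability proxy, not
  irreplaceability sensu conservation-planning theory.
- Boundary lengths ignore projection distortion (planar coordinates).
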