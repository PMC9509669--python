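# Methods

This note documents the models, conventions and numerical choices behind
`nichedyn`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Occurrence preparation

Records outside geographic bounds are rejected per record (logged, not
fatal). Records whose reported coordinate uncertainty exceeds the cut
(default 10 km) are dropped; records with *missing* uncertainty are kept,
because absence of the field is not evidence of imprecision and most
aggregated occurrence data lack it. Exact duplicate (lon, lat) pairs keep
the first record in input order.

Spatial rarefaction greedily retains records in a seeded random scan
order, keeping a record iff it lies at least the radius (default 10 km,
great-circle on a 6371-km sphere) from every record already kept. The
result is maximal (every dropped record conflicts with a kept one) and
idempotent; the seed is recorded in the set's provenance. Randomizing the
scan order mirrors the behaviour of the widely used thinning tools and
avoids systematic bias toward the input ordering.

## Derived climate layers

Growing degree days use the monthly truncated-sum estimator
`GDD = Σ_m max(0, T_m − base)·d_m` with base 5 °C and `d_m` the calendar
day count of month m (365-day year). A uniform-day variant (365/12 days
per month) is available for sensitivity analysis. The aridity index is
annual precipitation / annual potential evapotranspiration; PET ≤ 0 cells
are masked rather than propagated as infinities. Point extraction is
nearest-cell (no interpolation), matching cell-based SDM convention at
~10-km resolution; rows touching any masked layer are dropped with a
count.

## The niche-dynamics engine

**Ordination.** Correlation-matrix PCA (columns z-scored) of the pooled
background environments of both entities defines the two-axis space; the
calibration set is the full valid background rather than occurrences, so
the space reflects what is available, not what is occupied. Sign
convention: the largest-magnitude loading on each axis is positive. Grid
bounds are the background score range plus a 10% margin; occurrence
scores are clamped to the bounds; resolution defaults to 100 × 100.

**Kernel density.** A separable Gaussian product kernel with per-axis
bandwidth `h_j = σ_j·n^(−1/6)` (the 2-D reference rule), truncated at 4
bandwidths so the kernel has compact support and "positive density"
delimits a bounded region. Occurrence and background densities are each
normalized to unit mass; corrected occupancy density divides occurrence
density by availability on cells where availability is positive.

**Occupancy thresholding.** Two modes:

- `value` (default): occupied cells exceed the q-quantile of the positive
  corrected densities; q = 0 keeps every positive cell. This is the
  plainest reading of "occupied", and with the truncated kernel it is
  well defined.
- `mass`: occupied cells form the smallest highest-density region holding
  1 − q of the corrected mass. This mode is used wherever an estimate is
  compared against the generative oracle, because a 95% highest-density
  region is a geometrically stable object under both the true density and
  its kernel estimate.

**Indices.** S/U/E are occupied-cell set intersections/differences; BN =
U + S, BI = E + S on raw counts; BR = BI/BN; SI = 2S/(BN+BI). E and S are
reported as fractions of BI (so E + S = 1) and U as a fraction of BN —
the only normalization under which breadth ratios far above 1 can coexist
with expansion/stability fractions summing to one. Conservatism is
rejected iff BR > 1 *and* SI < 0.5, both strict.

## Synthetic landscapes and the truth oracle

Two latent environment fields are Gaussian-smoothed white noise
(smoothing length default 5 cells), standardized; every climate layer is
a linear mixture of the two, so the generated stack's intrinsic
environmental dimensionality is exactly 2 and PCA can recover the latent
plane up to an affine map. With the default 21 layers, twelve are
labelled monthly mean temperatures (°C, seasonal cycle included), one
annual precipitation and one PET (mm), so the derived-layer code paths
are exercised. The grid is equirectangular over ±60° latitude so
cell-area weighting matters.

Entities' suitability surfaces are Gaussians in latent space; occurrence
cells are drawn with probability proportional to suitability, by default
without replacement (with-replacement sampling is available and is the
right regime when the draw count approaches the count of effectively
suitable cells — several records per ~10-km cell is also what real
datasets contain). Default niches: native N((0.5, 0.25), 0.02·I),
introduced N((0.1, 0.0), 0.08·I) — a four-fold breadth ratio with a
centroid shift toward the availability centroid, while both entities
occupy a small enough share of climate space that presence/background
discrimination resembles real crop/progenitor studies.

`true_niche_partition` computes expected E/S/U/BR/SI by dense numerical
gridding (default 400²) of the two Gaussian densities, occupying each
niche's highest-density region at the stated mass quantile. Because E/S/U
fractions and BR are invariant under any affine map of the plane, the
oracle (in latent space) is directly comparable to the estimate (in PCA
space) — but only when the predictors feeding the PCA are the generator's
*linear* layers. The derived GDD and aridity layers are nonlinear in the
latents (truncation, ratio), bending the embedded surface, so
oracle-comparison tests use the linear layers; the full pipeline still
includes GDD/aridity, as an analysis of real data would.

What passing these tests shows: the estimation machinery recovers a known
two-dimensional Gaussian niche geometry through the full
raster→extraction→PCA→KDE→partition path (mean E/S/U within ±0.05 of
truth across 10 landscapes at n = 2000). What it does not show: behaviour
under real bioclim correlation structure, sampling bias, coastline-shaped
availability, or niches that are non-Gaussian in any ordination space.

## Ensemble SDMs

Pseudo-absences are drawn uniformly without replacement over valid
background cells excluding presence cells: per set, the presence count if
above 1,000, else 1,000; two sets by default. Each algorithm family is
fitted per pseudo-absence set on a random stratified 70/30 split and
evaluated on the held-out 30%: AUC by the rank statistic (ties counted
half), the MSS threshold by exhaustive scan over distinct scores
(presence predicted at score ≥ cutoff; ties broken by the smallest
cutoff, which favors larger predicted ranges), TSS = sensitivity +
specificity − 1 at that threshold. Retention is the literal OR of the two
gates (TSS > 0.6 or AUC > 0.8). The seven families map to scikit-learn
estimators (MLP, L2 logistic regression, random forest, spline-basis
logistic regression, linear discriminant analysis, decision tree,
gradient boosting) with fixed seeds and library-default hyperparameters;
the registry is pluggable. A non-converging member is logged and skipped.

All retained replicates from both pseudo-absence sets enter one ensemble
with weights proportional to TSS (negative TSS clipped to zero). The
ensemble MSS threshold is recomputed on the ensemble's scores at the full
evaluation point set (presences plus both pseudo-absence sets), and the
binary range is suitability ≥ threshold. Range area sums exact spherical
cell areas `R²·Δλ·(sin φ_top − sin φ_bot)`, R = 6371 km.

## Range and climate comparisons

Mapcurves GOF defaults to the exclusive-area convention (A and B net of
the intersection), under which identical maps score 1; the total-counts
convention (which caps a single-category GOF at 0.25) is available via a
flag since the two readings differ in the literature. Binary maps are
scored on the presence category; the multi-category sum is implemented
for generality. Range ratios are rounded to two decimals; percent
increase is (ratio − 1)·100 rounded to integer.

Mean climatic conditions are compared with Welch's unequal-variance
t-test (a pooled-variance option exists); per-predictor ranges (max −
min after min–max scaling against the pooled two-taxon reference) are
compared with a paired t-test across predictors. The "times wider"
aggregate defaults to the ratio of mean scaled ranges, with a
mean-of-ratios alternative, since either aggregation is defensible.

## Pipeline and determinism

`run_pipeline` chains clean → rarefy → derived layers → PCA/COUE → stats
→ per-entity ensembles → Mapcurves/ratios, writing a versioned JSON/CSV/
markdown report. Every stochastic stage derives its seed from the config
seed by fixed offsets, so a run is bit-reproducible; record counts after
each filter are logged and reported. Test and example configurations use
a 60 × 100 grid with 250–300 occurrences per entity and a three-algorithm
registry subset, sizes at which the full pipeline completes in a few
seconds while exercising every stage; the oracle-recovery analyses use
the full 120 × 200 default grid and n = 2000.

## Known limitations

- The occupancy threshold's `value` mode depends on the kernel truncation
  radius; narrow niches sampled at small n are systematically widened by
  smoothing, which inflates stability and shrinks the breadth ratio (the
  `mass` mode at a 5% quantile is the more stable estimator).
- Availability correction divides two kernel estimates and is noisy where
  background density is low; cells with zero availability are excluded
  rather than imputed.
- The seven algorithm families are analogues, not re-implementations, of
  any particular SDM platform's models; absolute TSS/AUC values depend on
  hyperparameters.
- Great-circle distances and cell areas assume a sphere, not an
  ellipsoid (errors < 0.6%).
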