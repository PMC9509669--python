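# nichedyn

Climatic niche dynamics and ensemble range modelling for paired taxon
comparisons — typically a cultivated crop against its wild progenitors
(e.g. maize vs. lowland and highland teosinte). The package asks two
questions biogeographers care about: *has the derived entity conserved the
climatic niche of its ancestor?* and *how much larger is its potential
range?* It answers them with the field's standard machinery, end to end,
and ships a synthetic-data generator with known niche truth so every stage
is testable without downloading occurrence or climate data.

## What it computes

**Niche dynamics (COUE scheme).** Occurrences of both entities are
projected onto the first two principal components of the climate
predictors (19 bioclim-style variables plus derived growing degree days
and an aridity index). Kernel-smoothed occurrence densities on a bounded
100 × 100 grid, corrected for background climate availability, yield
occupied-cell sets that are partitioned into

- **E** (expansion): cells occupied only by the derived entity,
- **S** (stability): cells occupied by both,
- **U** (unfilling): cells occupied only by the ancestor.

From the occupied-cell counts,

```
BN = U + S        (native niche breadth)
BI = E + S        (introduced niche breadth)
BR = BI / BN      (breadth ratio)
SI = 2S / (BN + BI)   (Sørensen similarity)
```

and niche conservatism is rejected when BR > 1 and SI < 0.5. E and S are
reported as fractions of BI, U as a fraction of BN.

**Ensemble SDMs.** Presences plus two sets of random pseudo-absences
(matching the presence count above 1,000, else 1,000) feed seven algorithm
families (neural network, regularized logistic regression, random forest,
spline-basis additive model, discriminant analysis, decision tree,
gradient boosting). Models are kept when held-out TSS > 0.6 or AUC > 0.8,
averaged with TSS-proportional weights, and the ensemble suitability is cut
at the sensitivity+specificity-maximizing (MSS) threshold to produce a
binary range map whose area is measured on the sphere.

**Range comparison.** Two binary ranges are compared with the Mapcurves
goodness of fit, `GOF = Σ_i C_i/(B_i+C_i) · C_i/(A_i+C_i)` (C shared
cells, A/B exclusive cells per category), plus range ratios and the
percent increases they imply. Climatic conditions at occurrences are
compared with Welch t-tests on the dominant PC predictors and a paired
t-test on min–max-scaled per-predictor ranges.

## Worked example

`examples/03_niche_dynamics.py` builds a synthetic landscape whose crop
niche is four times broader than the progenitor's and shifted toward the
availability centroid, then estimates the partition from 2,000 occurrences
per entity:

```
PC1 explains 57.5%, PC2 42.5% of climate variance
top PC1 predictors: ['bio7', 'bio4', 'bio6']
estimated: E=0.77 S=0.23 U=0.13 BR=3.78 SI=0.36
truth:     E=0.79 S=0.21 U=0.16 BR=4.00 SI=0.34
verdict: not_conserved (BR>1 and SI<0.5 rejects niche conservatism)
```

The estimated expansion/stability/unfilling fractions track the
generative truth to about ±0.03; the breadth ratio near 4 with Sørensen
similarity 0.36 rejects niche conservatism, as designed into the scenario.
The other scripts in `examples/` walk through occurrence cleaning and
rarefaction, single-taxon ensemble SDMs, Mapcurves comparison, and the
one-call pipeline (`run_pipeline`), which chains every stage and emits a
JSON/CSV/markdown report.

A thin CLI wraps the same functions:

```bash
nichedyn synth --seed 1 --outdir landscape     # generate rasters + occurrence CSVs
nichedyn prep landscape/crop.csv               # clean + 10-km rarefaction
nichedyn run config.yaml                       # full pipeline from a YAML config
nichedyn rangecmp mapA.asc mapB.asc            # Mapcurves GOF + range ratio
```

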