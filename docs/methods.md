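# Methods

## Scope

`pescore` is a desk-scale implementation of a global extinction-risk
pre-assessment pipeline. Everything runs on a synthetic world with a known
threat-generating process; no external data are downloaded. The purpose is
to verify the *machinery* — feature extraction, filtering rules, stacked
learning, evaluation, spatial aggregation — against ground truth, not to
reproduce real-world risk estimates, which require the real range maps,
occurrence archives and stressor layers.

## Grid conventions

All spatial work happens on a fixed global 0.5° grid (720 × 360, WGS84),
indexed row-major from the north-west corner. Cells are half-open in both
axes: a coordinate on a cell edge belongs to the cell starting eastward /
extending southward, so every point maps to exactly one cell. Cell areas
use the authalic sphere (R = 6371.0072 km). Coordinates closer than
~1e-9° to a cell edge can be absorbed by float rounding against the 180°
offset; that is below any ecological resolution and documented in the
property tests.

## Synthetic world

* **Stressor layers.** Causal layers are Gaussian-smoothed seeded white
  noise (σ = 6 cells, longitude-periodic), standardised; their lag-1
  spatial autocorrelation is ≈ 0.8. Noise layers are unsmoothed white
  noise (autocorrelation ≈ 0). Two count-like Poisson layers with smooth
  hotspot structure stand in for dams and power plants. Default roster:
  3 causal + 20 noise + 2 count layers; 2% of value-layer cells are
  NaN-holed to exercise the missing-data path.
* **Species.** 2000 by default. Ranges are axis-aligned ellipses with
  log-uniform area between 3 and 400 equivalent cells (marine ×3, because
  marine ranges are spatially larger), centres uniform in lon × lat
  ∈ [−70°, 70°]; 10% get a second "breeding" polygon and 5% a decoy
  non-native or non-extant polygon that the rasteriser must ignore.
  Taxonomy is drawn from a fixed 2-kingdom / 21-family pool; domain sets
  (terrestrial/freshwater/marine combinations) from fixed weights giving
  ~35% marine species. Habitat counts and country counts (a seeded 24 × 12
  rectangular partition of the grid) are label-independent covariates.
* **Labels.** True threat probability is logistic with intercept −1.1 and
  standardised coefficients (1.5, −1.2, 1.0) on the range-cell means of
  the causal layers — strong effects, |β| ≥ 1, giving ~30% threatened,
  comparable to the class balance in real assessed taxa. Threatened
  species draw a category uniformly from {VU, EN, CR}, the rest from
  {LC, NT}; the legacy LR/* codes are handled by the reclassifier and
  covered in tests. 20% of species are relabelled DD (sampling weight
  (1/range cells)^0.5, since data-poor species tend to have small ranges —
  the strength of that covariate shift is a modelling choice, not an
  observed value); 1% are relabelled EX/EW; 5% are flagged as outdated
  assessments. The pre-relabelling category and the Bernoulli draw are
  kept aside as ground truth.
* **Occurrences.** 85% of species have points; counts are log-normal
  (median ≈ 12, capped at 500), placed uniformly inside the resident
  ellipse, years 2010–2020.

What the generator does **not** emulate: real biogeography and coastlines,
spatially clumped occurrence effort, taxonomic signal in threat status,
range-shape complexity, and correlated stressor layers. Passing tests
therefore demonstrate that the pipeline recovers a known signal under
realistic bookkeeping (missingness, imbalance, heterogeneous range sizes),
not that real Red List predictions would attain the same accuracy.

## Feature extraction

A cell belongs to a range iff its rectangle has a positive-area
intersection with any native + extant seasonal polygon (union over
seasons); a range too small to cover any cell falls back to the centroid
cell of its largest polygon, so no species vanishes. Zonal statistics are
min/max/mean/median over non-missing cell values; an even-count median is
the mean of the two middle values. Species without occurrence points get
`n_occurrence_points = 0` but *missing* (not zero) occurrence-derived
columns, later imputed — missingness is information here, mirroring the
~5–8% NA rate the full table shows. Range extent is reported both as a
cell count and as geodesic km², since the natural unit is ambiguous.
Imputation is hot-deck: each missing entry is a seeded uniform draw from
the column's observed values *in the training rows only*; the fitted pools
are reused for test and DD rows, so no test information leaks.

## Feature selection

One-shot Boruta: in each of R = 50 runs, every candidate column gets an
independently permuted shadow copy; a seeded random forest (60 trees,
√p features per split) is fitted on originals + shadows and scored by
out-of-bag permutation importance (impurity importance is biased toward
high-cardinality features and would distort the shadow comparison); a
feature hits iff its importance strictly exceeds the best shadow's.
Decisions come from a two-sided exact binomial test of the hit count
against Bin(R, ½) at α = 0.01; tentative features are dropped. One-hot
blocks are confirmed as a block if any member is confirmed.

## Stacking

The roster is fixed (no AutoML search): L2 logistic regression on
standardised inputs, random forest (120 trees), histogram
gradient-boosted trees (120 iterations), extremely randomised trees
(120 trees). Stratified 10-fold CV produces the out-of-fold probability
matrix; the minority class is oversampled (seeded, with replacement)
inside each fold's training part only — never validation folds, never the
test set.

The meta-learner minimises mean logistic loss + λ·Σβ subject to β ≥ 0 with
a free intercept. On the non-negative orthant the L1 penalty is linear, so
the objective is smooth there and bound-constrained L-BFGS solves it
exactly, parking weak learners at exactly zero. λ runs over 25 log-spaced
values from the KKT bound λ_max (the smallest λ that zeroes every
coefficient) down three decades; the choice is 5-fold CV log-loss with the
1-SE rule — the most regularised model within one standard error of the
best — which is what produces sparse ensembles. Base models are refit on
the full oversampled training set for prediction; the OOF matrix is used
only to fit the meta-model (standard super-learner protocol). The decision
threshold maximises F1 on the out-of-fold super-learner scores (ties go to
the smallest threshold); it is a documented knob, chosen because the
published confusion matrices show the asymmetric PPV/NPV pattern a 0.5 cut
does not produce.

Two partition schemes are trained: (1) all species together, and
(2) separate marine / non-marine models (feature selection re-run per
model on its own training data; a subset under 50 training rows is skipped
with a warning). Partition choice uses the unweighted mean AUC of
cross-validated scores across taxonomic classes with ≥ 5 labelled members;
ties and the no-eligible-class fallback go to the pooled partition.

## Evaluation

Confusion-based metrics are exact ratios; zero-denominator metrics are
reported as undefined, never as 0 (display rounding is half-up to 2 dp).
AUC is the rank statistic (ties count ½); AUC_PR is step-wise average
precision without linear interpolation; Gini ≡ 2·AUC − 1. Permutation
importance is the mean AUC loss on the test set over 50 seeded
permutations of one column at a time, with the baseline computed once.
The re-assessment validation mimics checking the classifier against a
later Red List release: the generator's true categories are revealed for
a held-out DD slice (123 species by default) and the same metric pipeline
is applied; an overlap with training ids is an error.

## Aggregation

Presence is range-cell membership under the extraction convention. The
DD-fraction map is (# DD present and predicted threatened)/(# DD present),
masked (raster nodata, never zero) where no DD species occurs. The
percent-change map is 100·(mean_all − mean_DS)/mean_DS per cell, masked
where no DS species is present; DS species contribute their
*model-predicted* PE score (switchable to a 0/1 category encoding), since
pooling predicted with categorical values would conflate scales.

## Problem sizes and determinism

The default study is 2000 species with the compact modelling feature set:
per-layer range-cell means (the channel the generating process acts
through — 3 causal + 20 noise columns) plus all non-zonal covariates and
the two point-count predictors; the full 4-statistic × 2-support table is
always built and written by the extraction stage, and the full-table path
is exercised in the test suite at smaller n. One full `run-all`
(both partitions, R = 50, 10 folds) takes ~1.5 minutes on one CPU.
Every stochastic step draws from a per-stage substream of the single run
seed, and reruns are byte-identical (hash-checked in the tests).

## Known limitations

* Ellipse ranges cannot produce fragmented or coastline-bounded ranges;
  range topology effects on zonal statistics are untested.
* The generator gives taxonomy no causal role, so the pipeline's handling
  of phylogenetic signal is only exercised syntactically.
* The logistic truth favours the GLM base learner; tree learners dominate
  only under non-additive truths, which the default study does not plant.
* The meta-learner's λ grid spans three decades below λ_max; degenerate
  OOF matrices (all-constant columns) keep a defined path but are only
  warned about.
* Antimeridian-crossing ranges are clipped at ±180° rather than wrapped.
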