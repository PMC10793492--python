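# Methods

This note documents the models, parameter choices and numerical
conventions behind `tilarch`, and what the synthetic studies do and do
not demonstrate about real data.

## Cell-cluster subgraphs and the 350-feature registry

Within one tile, cells of a family (TIL or non-TIL) are nodes of a graph
with an edge whenever the Euclidean distance between two cells is **at
most** τ (ties at exactly τ are included). Clusters are the connected
components; singletons are clusters of size one. τ defaults to 50 µm and
is a single configuration value used identically everywhere. The tile's
compartment (epithelium or stroma) combined with the TIL flag encodes
the four cell families.

The tile descriptor is a named registry of 350 features: 70 base
measurements × 5 within-tile summary statistics (mean, median, min, max,
population std). The base measurements are, per family: ten per-cluster
distributions (member count, convex-hull area and perimeter, hull
density, major-axis extent, RMS spread, circularity, covariance aspect
ratio, mean within-cluster nearest-neighbor distance, nearest
other-cluster centroid distance), six per-cell distributions
(same/cross-family nearest-neighbor distances and neighbor counts within
25 and 50 µm), and six tile scalars (count, density, cluster count,
clustered fraction, largest-cluster fraction, hull-area fraction);
plus 26 cross-family interplay measurements (nearest cross-cluster
centroid distances both ways, hull IoU with the nearest opposing
cluster, kNN mixing indices at k ∈ {3, 5, 10} for TIL / non-TIL / all
cells, and 13 composition scalars such as TIL fraction, count and hull
area ratios, cross-family edge fraction, and the fraction of each
family's cells inside the opposing family's hulls). The registry is
data-driven — downstream stages reference features by name only — so the
composition can be replaced wholesale without code changes. The
headline measure "average TIL cluster area" is
`mean_til_cluster_hull_area`.

Tile scalars are passed through the same five summary statistics as the
distributions (mean = median = min = max = value, std = 0); this keeps
the 70 × 5 layout uniform at the cost of some redundant columns, which
the LASSO stage tolerates by construction.

### Degenerate-geometry conventions

- Convex hull of < 3 non-collinear points: area 0; hull density,
  circularity and aspect ratio are then undefined and carry NaN.
- Hull IoU with a zero-area union: 1 if the geometries coincide, else 0.
- Ratios with a zero denominator: a configurable finite cap (default
  100) when the numerator is positive, NaN for 0/0.
- Empty distributions summarize to 0 for count-like measurements and
  NaN for geometry/fraction/ratio measurements. NaN is the documented
  sentinel; nothing is silently dropped.

## Patient aggregation

Each of the 350 tile features is aggregated per compartment over all of
a patient's tiles (pooled across slides) with mean, median, min, max,
range (max − min) and variance, for 4,200 = 6 × 2 × 350 named patient
features. Variance uses the population (n) denominator so duplicating
every tile changes nothing. NaN sentinels are skipped per feature
(pairwise deletion); a compartment with no tiles produces an all-NaN
block. Imputation is deferred to model fitting, where the cohort median
of the **training split** fills missing values — the standardizer and
imputer never see test data.

## LASSO-Cox risk models

Features are z-scored (training mean/sd, ddof = 0); constant columns are
dropped with a warning. The L1-penalized Cox path is fitted with
scikit-survival's coordinate-descent solver over ~30 penalties; the
penalty is chosen by minimizing the mean 10-fold cross-validated
partial-likelihood deviance (−2 × Breslow partial log-likelihood of the
held-out fold), the minimum-deviance rule rather than the 1-SE rule.
The risk score is the sparse linear predictor; an all-zero coefficient
vector is flagged as a null model.

The stratification threshold Th scans 81 score quantiles between the
10th and 90th percentile and keeps the admissible cut (each stratum
≥ 10% of patients and ≥ 2 events) that maximizes the two-strata
separation |log HR|; for a correctly oriented risk score this is plain
HR maximization, and the absolute value makes tuning symmetric under a
score sign flip. Ties break toward the median cut. The two-group Cox
model inside the scan is a scalar Newton solver with Efron tie handling
(validated against lifelines to 6 decimals); multivariable and
univariate adjusted analyses use lifelines directly (Efron ties, Wald
CIs, listwise deletion of missing covariates with a logged count,
constant/collinear covariates dropped with a warning). C-index is
Harrell's, via scikit-survival.

## Consensus clustering and subtype agreement

The merged matrix takes the deduplicated union of the three model
supports (order of first appearance), z-scored. Consensus clustering
draws 500 subsamples of 80% of patients, clusters each with k-means at
the forced K, and records for every patient pair the fraction of
co-sampled runs in which they co-clustered; final labels cut the
average-linkage dendrogram of (1 − consensus) at K. Cluster-to-subtype
matching maximizes total agreement on the contingency table (Hungarian
assignment, one-to-one), making recall/precision invariant to cluster
relabeling and immune to many-to-one collapse.

`til_profile_matrix` provides a fixed 14-column TIL-profile summary
(7 density/cluster-geometry/mixing summaries × 2 compartments),
log1p-transformed before z-scoring because immune infiltration varies
multiplicatively across phenotypes, with z-scores winsorized at ±3 sd so
a few immune-cold patients with unstable fraction estimates cannot
dominate the distance structure.

## Genomics

- Risk-correlated genes: Pearson r with two-sided t-test p, filter
  p < 0.05; zero-variance genes excluded with a log entry.
- Differential expression: two-sided Wilcoxon rank-sum per gene,
  Benjamini–Hochberg FDR across genes, log2FC =
  log2((mean_high + c)/(mean_low + c)) with pseudocount c = 1; selection
  requires q < 0.05 and |log2FC| > 1.
- ssGSEA: genes ranked by descending expression (average ranks weight
  ties); the running sum rises by rank^α (α = 0.75) normalized over the
  set at members and falls by 1/(N − N_set) at non-members; the activity
  index is the integral of the running sum divided by the range between
  the integrals attained when the set occupies the top versus the bottom
  of a tie-free ranking. That range is a constant of (N, N_set, α), so
  indices are comparable across samples and across gene sets. Adding a
  constant to one sample's expression leaves its ranks, hence its index,
  unchanged.
- Wilcoxon tests are exact for groups of ≤ 10, otherwise the
  tie-corrected normal approximation with continuity correction.
- Mutation association: genes with < 3 mutants or < 3 wild-type are
  skipped with a log entry; otherwise Wilcoxon on risk and log-rank on
  PFS. Per-gene survival uses a median expression split with ties
  assigned to the low group; a split with ≥ half the samples tied at the
  median is flagged degenerate.
- Multiple-testing correction is applied within each analysis family
  (e.g. across genes in one DE run), not across analyses.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not histology. TIL positions follow a Thomas process — Poisson parents
(intensity κ per mm², simulated on a window padded by 4σ so edge
clusters contribute), Poisson(µ) offspring per parent, isotropic
Gaussian offsets σ — because the pipeline's headline features are TIL
cluster geometry and a cluster process gives direct parametric control
of it. Non-TILs are homogeneous Poisson. Default densities (TIL 300,
epithelial non-TIL 800, stromal non-TIL 500 per mm²; µ = 15, σ = 25 µm)
are order-of-magnitude choices typical of H&E tile cellularity; no
published distributional facts back them and no conclusion should rest
on their exact values.

Four named archetypes — one per molecular subtype CNH/CNL/MSI/POLE —
rescale the TIL process (intensity, offspring, dispersion), with immune
infiltration increasing from CNH (cold) to POLE (hot) in the default
set; `separated_archetypes()` places the four subtypes in distinct
directions of the profile space for recovery studies, and
`uniform_archetypes()` removes the coupling entirely. A per-patient,
per-compartment lognormal jitter (σ = 0.25 by default) of the TIL
parameters creates genuine between-patient feature variance;
epithelial and stromal jitters are independent, which is what lets
compartment-specific risk signals stay population-specific.

Patient risk is an explicit linear predictor over the **realized,
cohort-standardized pipeline features** (optionally different effect
vectors per population), so the prognostic signal is by construction
recoverable by the modeling stack rather than an approximation of it.
PFS times are exponential with hazard h0·exp(risk) (h0 = 0.02/month,
median ≈ 35 months at zero risk) under independent exponential censoring
(0.015/month, ≈ 40% censoring); OS uses a lower baseline hazard
(0.012/month). Expression couples n_risk_genes to the standardized risk
at Pearson strength `gene_effect` on a linear scale; mutations follow a
logistic model in the standardized risk (default log-odds −1, i.e.
protective mutations enriched in low-risk patients). All randomness
derives from one seed expanded into per-patient substreams
(`SeedSequence.spawn`), so every object is a pure function of
(config, seed) and patient order never changes results.

What passing the synthetic studies shows: the implementation computes
the intended quantities (exact oracle agreement), the statistics are
calibrated under their nulls, and the stack recovers signals it is
designed to detect at realistic dimensionality. What it does not show:
performance on real H&E-derived cell maps, whose segmentation errors,
staining variation, spatial inhomogeneity and non-exponential hazards
the generator deliberately does not model.

## Problem sizes used in the shipped studies

Acceptance-style studies run at deliberately desk-scale sizes chosen as
the package's own defaults: 100 random tiles of ≤ 200 cells for oracle
equivalence; n = 300 patients × 4,200 features for LASSO recovery
(5 planted effects, |β| = 1, 10 folds, 10 seeds); 1,000 null simulations
at n = 40 for log-rank calibration; a 210-patient two-population cohort
for the cross-population C-index gap; an 80-patient cohort with four
separated archetypes and 250 consensus resamples for clustering
recovery; 1,000 genes with
10 planted four-fold changes at n = 30 per group for DE recovery.

## Known limitations

- The feature registry is one defensible composition of the 350-feature
  contract; other compositions are plausible and swappable.
- The threshold-tuning grid and admissibility rules guard against
  degenerate HR maximization but are conventions, not theory.
- Exponential survival/censoring makes calibration checkable in closed
  form but understates real-world hazard heterogeneity.
- Consensus clustering uses k-means base learners; strongly non-convex
  cluster shapes would need a different base learner.
- The CLI covers the common paths; programmatic use is the primary
  interface.
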