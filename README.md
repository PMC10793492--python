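# tilarch

Spatial profiling of tumor-infiltrating-lymphocyte (TIL) architecture in
endometrial cancer tissue, with population-specific survival modeling and
genomic linkage.

Endometrial cancer kills African American (AA) women at roughly twice the
rate of European American (EA) women, and prognostic models trained on
predominantly EA cohorts can fail to transfer. `tilarch` implements a
pipeline for studying this problem from H&E-derived cell maps: it turns
per-tile centroids of TILs and non-TILs in epithelial and stromal tissue
compartments into quantitative immune-architecture descriptors, fits
sparse Cox survival models per population, and connects the resulting
morphologic risk scores to molecular subtypes, gene expression and
somatic mutations. A fully parameterized synthetic-cohort generator with
known ground truth makes every stage testable without any patient data.

## The pipeline

1. **Tissue masks** (`tilarch.masks`) — epithelium/stroma probability
   rasters are thresholded, connected components smaller than 2,000 px
   are removed, a QC mask is intersected in, and the image is gridded
   into compartment-labeled ROI tiles.
2. **Cell-cluster subgraphs** (`tilarch.features`) — within a tile, cells
   of one family are linked when their Euclidean distance is at most a
   threshold τ (default 50 µm); connected components of this proximity
   graph are the cell clusters. Cluster geometry (convex-hull area,
   extent, density, spacing), per-cell neighborhoods and TIL/non-TIL
   interplay (cluster distances, hull IoU, kNN mixing) are summarized
   into **350 named features per tile** (70 base measurements × 5
   within-tile statistics).
3. **Patient aggregation** (`tilarch.aggregate`) — each tile feature is
   summarized per compartment over all of a patient's tiles with six
   statistics (mean, median, minimum, maximum, range, variance), giving
   **4,200 features per patient** (6 × 2 × 350).
4. **Prognostic models** (`tilarch.survival`) — after a 2:1 train/test
   split, population-specific models M_AA and M_EA and a
   population-agnostic M_PA are fitted by LASSO-Cox: z-score
   standardization (training statistics only), an L1-penalized Cox path
   with the penalty chosen by minimizing 10-fold cross-validated
   partial-likelihood deviance, a sparse linear risk score
   s(x) = Σ_j β_j z_j(x), and a threshold Th tuned on the training data
   to maximize the hazard ratio between the two risk strata. Evaluation
   reports Kaplan–Meier curves, the log-rank test, HR with Wald 95% CI,
   Harrell's C-index, and covariate-adjusted Cox tables.
5. **Subtype clustering** (`tilarch.clustering`) — the unique features
   supporting the three models are merged into one matrix and
   consensus-clustered (subsampled k-means aggregated into a
   co-assignment matrix, hierarchically cut at a forced K, e.g. K = 4
   for the CNH/CNL/MSI/POLE molecular subtypes); clusters are scored
   against subtype labels with recall/precision under optimal one-to-one
   matching.
6. **Genomic linkage** (`tilarch.genomics`) — risk-correlated genes
   (Pearson P < 0.05), differential expression between risk strata
   (Wilcoxon rank-sum, BH FDR < 0.05 and |log2FC| > 1), single-sample
   gene-set enrichment activity indices, mutation-vs-risk association,
   and per-gene survival at the median expression split.
7. **Synthetic cohorts** (`tilarch.synthetic`) — TILs follow a Thomas
   cluster process, non-TILs homogeneous Poisson; molecular-subtype
   archetypes rescale the TIL cluster process; survival is exponential
   with hazard h0·exp(risk) where the risk is an explicit linear
   predictor over the realized pipeline features; expression and
   mutations are coupled to the same latent risk.

## Worked example

```python
import numpy as np
import tilarch as ta

cfg = ta.SimConfig(
    n_patients=60, tiles_per_patient=(3, 4), tile_size_um=400.0,
    effect_vector={"mean_stroma_mean_til_cluster_hull_area": 1.2},
    n_genes=100, seed=7)
cohort = ta.simulate_cohort(cfg)

X, surv = cohort.features, cohort.survival_frame()
split = ta.split_cohort(surv, seed=7)
model = ta.fit_model(X.loc[split.train_ids],
                     surv[surv.patient_id.isin(split.train_ids)],
                     folds=10, seed=7, label="M_PA")
report = ta.evaluate(model, X.loc[split.test_ids],
                     surv[surv.patient_id.isin(split.test_ids)])
print(f"{model.label}: {len(model.support)} features in support")
print(f"test C-index {report.cindex:.3f}, log-rank p {report.logrank_p:.2e}")
```

prints

```
M_PA: 9 features in support
test C-index 0.925, log-rank p 5.45e-06
```

meaning the LASSO kept 9 of the 4,200 features, the continuous risk
score orders the held-out patients' progression times clearly better
than chance (C = 0.5 is random, 1.0 perfect), and the tuned threshold
splits the test cohort into two strata with significantly different
progression-free survival.

The same objects feed the rest of the pipeline: `ta.til_profile_matrix`
+ `ta.consensus_cluster` for subtype structure, and
`ta.risk_correlated_genes` / `ta.de_between_risk_groups` /
`ta.ssgsea` for the genomic analyses, using `cohort.expression` and
`cohort.mutations`.

A thin CLI mirrors the library:
`tilarch simulate | mask | features | aggregate | fit | evaluate |
cluster | genomics` (see `tilarch --help`).

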