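# Methods

## Problem and data model

Multiplex tissue imaging (here, tissue-based cyclic immunofluorescence,
t-CyCIF) quantifies a fixed marker panel per segmented cell, with spatial
coordinates. Markers can fail (tissue loss, probe failure) or simply not be
in the panel; `mtimpute` predicts a withheld marker's per-cell abundance
from the remaining markers, optionally augmented with the mean abundance of
spatial neighbors.

The in-memory container is a `SingleCellTable`: one row per cell with
`cell_id`, `patient_id`, `biopsy_id`, `timepoint` (pre/post-treatment),
centroid `x`/`y` in µm, and one intensity column per panel protein.
Bio-morphological quantification columns (area, extent, orientation, ...)
are dropped at read time; coordinates are kept for the spatial features.
The default panel is a 16-marker breast-cancer panel, 8 lineage markers
(CD45, αSMA, eCadherin, CK19, CK14, CK17, CK7, Vimentin) and 8 functional
markers (Ki67, pERK, PR, EGFR, p21, pRB, AR, HER2), assigned to 4 staining
rounds of 4 markers each in panel order. The round assignment is a package
default — real experiments should supply their own panel YAML with the
actual acquisition rounds, since round grouping determines which proteins
are withheld together in multi-protein imputation.

## Preprocessing

Intensities are min-max scaled per protein to [0, 1], so error magnitudes
are comparable across markers. Two scaling scopes are provided because the
right choice is genuinely open:

* `train_only` (default): extrema fitted on the training partition only and
  applied to test data, preventing test-set leakage through the scaler;
* `global`: extrema fitted on the full cohort before splitting.

Out-of-range values under `train_only` are clipped to [0, 1] — consistent
with clipping of model outputs, and necessary for MAE on the unit scale to
be meaningful. A constant (degenerate) protein scales to 0, which keeps the
range valid and encodes "no information".

## Imputer families

All models receive either the P own-protein columns (radius 0) or P own +
P neighbor-mean columns (one radius per model; never several radii at
once), with the target's own column excluded.

* **Null**: imputes the training-set mean of the target. Its MAE on any
  test set is, by identity, the mean absolute deviation of the test target
  about the train mean; any useful model must beat it.
* **Regularized linear**: elastic net with internal 5-fold cross-validation
  over 50 penalty strengths and mixing values {0.1, 0.5, 0.9}
  (scikit-learn `ElasticNetCV`). One model per target protein.
* **Boosted trees**: LightGBM regression, 100 rounds, ≤31 leaves, learning
  rate 0.1, single-threaded deterministic mode. One model per target.
* **Autoencoder**: an encoder–decoder multilayer perceptron,
  input (P or 2P) → 16 → latent 8 → 16 → P outputs, ReLU hidden units,
  Adam, early stopping on a held-out 10% of training cells, at most 300
  epochs (a deliberate compute cap; reconstruction quality at the cap is
  validated against the null model in the tests). The latent dimension must
  be strictly below P. Outputs are clipped to [0, 1] (the output layer is
  linear; clipping plays the role a sigmoid output unit would). One model
  reconstructs all P proteins, so a single fit supports both single-protein
  and round-group imputation.

All hyperparameters above are defaults chosen for desk-scale data and are
overridable via `ImputerSpec.hyperparameters`.

### Iterative autoencoder imputation

Targets are first replaced by the training-set mean (default) or zero.
Each cycle runs one full encode–decode pass and writes the decoded target
values back into the input; non-target columns are never modified. After
`n_iter` cycles (default 10) the final estimate is the per-cell mean of the
last `window` iterations (default 5, i.e. iterations 6–10). `window` is
configurable: `window=6` averages iterations 5–10 instead, and
`n_iter=1, window=1` reduces the procedure exactly to a single decode pass.
With an identity reconstructor the loop is a fixed point at the init value.

When spatial features are used, the neighbor-mean column of the target
protein is **kept** as a predictor by default: it is computed from the
observed values of neighboring cells, which in the intended application
(inferring an unassayed marker from a reference cohort's neighborhoods) are
taken as known. `exclude_target_neighbors=True` gives the stricter variant
in which no function of the target marker enters the predictors.

## Spatial neighborhood features

Neighbors are all other cells of the same biopsy within a Euclidean radius
(closed ball; ties at exactly the radius are included). Candidate radii are
{15, 30, 60, 90, 120} µm with 0 encoding the non-spatial baseline. The
feature per protein is the arithmetic mean over neighbors, computed on
scaled intensities so own and neighbor features share the unit scale; a
cell with no neighbors gets an all-zero feature row. A kd-tree accelerates
the search but the result is contractually identical to the all-pairs
computation (asserted to 1e-12 in the tests). Neighborhoods never cross
biopsy boundaries, since tissue sections are physically distinct.

## Cross-validation and replication

The unit of validation is the patient. In `across_patient` mode each fold
holds out all biopsies of one patient; in `within_patient` mode one biopsy
per patient trains and the sibling biopsy tests (both orientations).
Scaling, spatial-feature construction, and model fitting all run strictly
inside the training partition of a fold; the leakage audit fingerprints
every (biopsy, cell) key that entered fitting and checks disjointness from
the test keys.

A four-patient cohort yields only four leave-one-out folds, so replicates
vary the model seed and draw a fresh 80% subsample of training cells
(`subsample_frac`, 1.0 disables), giving the ≥30 independent runs per
condition that rank-based testing needs. All seeds derive deterministically
from one base seed via a stable hash of the run context, so a run is
reproducible byte-for-byte for the deterministic families.

Per-protein performance is the mean over per-replicate MAE values. Model
pairs are compared with two-sided Mann-Whitney U tests on per-replicate
MAE; Benjamini-Hochberg adjustment is applied across all comparisons
requested in one call (the correction family is a user decision; the
package does not pool across calls). Pearson correlations of constant
vectors are recorded as undefined (NaN) and excluded from averages rather
than coerced to 0.

## Concordance evaluation

Cluster-level agreement uses k-means (default k = 8, fixed seed, identical
settings on both tables) with ARI and AMI between the two partitions, and
silhouette scores on Euclidean distance over scaled proteins (subsampled to
10,000 cells, seeded; full computation by flag). k-means is a pragmatic
default for a centroid-based partition, not an inference about any
particular upstream phenotyping pipeline.

Phenotype calling is ordered threshold gating on lineage markers: the first
rule whose marker exceeds its threshold assigns the label, else a fallback.
Phenotype agreement reports ARI, AMI, and the Jaccard index
macro-averaged over labels (|a_ℓ ∩ b_ℓ| / |a_ℓ ∪ b_ℓ|, mean over ℓ); a
pooled micro-average is also available.

## Treatment-timepoint experiment

A two-step design measures whether imputed values retain the biology needed
to classify cells as pre- vs post-treatment. Step 1 tiles each biopsy into
300 µm × 300 µm floor-quantized tiles, computes mean expression per tile
(the studied protein excluded), and keeps only tiles whose timepoint a
boosted-trees tile classifier predicts correctly — training tiles judged by
out-of-fold prediction (5-fold, stratified; a resubstitution mode exists
for comparison), test tiles by the classifier fitted on all training tiles.
Out-of-fold judging avoids optimistically selecting tiles the classifier
has memorized. Step 2 trains a boosted-trees cell classifier on cells of
the selected tiles under three input variants: ground truth, the protein's
column removed, and the column replaced by non-spatial boosted-trees
imputed values (for training cells these are resubstitution predictions of
the fold's imputer; for test cells, genuine out-of-sample predictions).

Evaluation is leave-one-biopsy-out with the test patient's other biopsy
also excluded from training. Seeds derive from (protein, split, replicate)
and never from the variant, so the three variants of a protein are paired
run-for-run. A label-shuffling switch permutes the cell-level timepoint
labels (seeded) as a chance-level control; because a single test biopsy is
single-class, the shuffled control is averaged over several replicates.

## Synthetic cohort generator

Real t-CyCIF cohorts of this design are access-restricted, so the package
ships a generator that emulates the statistical structure the analysis
relies on — it is the test bed, not a simulation of microscopy. The
paper-like preset builds 4 patients × 2 biopsies (pre/post), default 2,000
cells per biopsy in a 1 × 1 mm field.

Per biopsy, 10 niche centers are placed uniformly; cells are assigned a
niche, positioned isotropically around its center (σ = 60 µm, clipped to
the field), and typed from niche-specific mixing proportions
(Dirichlet α = 0.7 over 5 cell types: immune, stromal, tumor-luminal,
tumor-basal, mesenchymal). Expression is assembled additively on the [0,1]
scale: a cell-type archetype value per marker, a per-patient offset
(σ = 0.03), linear dependency terms evaluated on the parents' realized
values, a neighborhood term, a treatment shift, and Gaussian noise
(σ = 0.05 default), clipped to [0, 1]. Clipping is logged and stays below
5% under the preset. Everything derives from one root seed with per-biopsy
substreams.

Preset structure, chosen once to make every pipeline stage testable:

* **Dependencies** — pRB = 0.5·Ki67 + 0.3·pERK + 0.2·EGFR,
  AR = 0.6·PR + 0.4·HER2 (plus the target's own base and noise). Because
  targets are evaluated on realized parent values, least squares on the
  generated cells recovers these coefficients, which is the generator's own
  correctness oracle.
* **Neighborhood-driven marker** — eCadherin gains 0.35 × (fraction of
  tumor-luminal cells within 30 µm), computed during generation. This makes
  spatial features *causally* informative, so the spatial-benefit property
  (trees at 30 µm beating radius 0) is a testable consequence of the
  construction rather than an accident.
* **Hard markers** — CK19 and PR carry observation noise σ = 0.22
  (vs 0.05), reproducing the situation where high-variance markers are the
  hardest to impute.
* **Treatment effect** — +0.15 on Ki67 and pERK in post biopsies (taken at
  progression, when proliferative signalling has escaped CDK4/6 blockade);
  pRB inherits a partial shift through its parents, which is what makes the
  imputed-variant treatment experiment informative.

What the generator does **not** emulate: non-Gaussian intensity
distributions and heavy tails, segmentation errors, staining-round batch
effects, illumination artifacts, cell-shape covariates, and realistic
cell-type frequencies. Passing tests therefore show the algorithms are
implemented correctly and behave as designed under known structure — not
that any particular accuracy will be attained on real cohorts.

## Numerical choices and degenerate inputs

* All imputed values, everywhere, are clipped to [0, 1].
* Boundary cells at exactly the neighbor radius are neighbors (closed
  ball); tile intervals are half-open, so x = 300 with 300 µm tiles falls
  in tile 1.
* Constant truth or prediction vectors: Pearson r undefined (NaN), never 0.
* Empty neighbor sets: zero-filled features with `neighbor_count` 0.
* Single-protein models refuse multi-protein targets; the autoencoder
  refuses a latent dimension ≥ P; silhouette refuses a single cluster;
  across-patient splitting refuses single-patient cohorts.
* LightGBM runs single-threaded deterministic; the MLP uses a fixed seed —
  identical base seeds reproduce metrics CSVs byte-for-byte.

## Problem sizes

Defaults in the shipped tests and the acceptance script use 300–2,000
cells per biopsy (2,400–16,000 cells per cohort), 2–20 replicates, and a
5-protein benchmark target set. These sizes were chosen so the full
pipeline exercises every code path at interactive speed; all of them scale
up by configuration only.

## Known limitations

* The autoencoder is a dense MLP; no denoising/variational variants and no
  GPU path.
* The tile classifier and cell classifier share one family (boosted trees);
  only the family is configurable, not per-stage hyperparameters.
* Multi-protein imputation groups are staining rounds only.
* The generator's additive-Gaussian expression model cannot produce the
  bimodal marker distributions common in real gating; the shipped gating
  thresholds are preset-specific.
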