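# mtimpute

Single-cell protein-abundance **imputation** for multiplex tissue imaging
(MTI) feature tables, with spatial-context features, patient-wise
cross-validated benchmarking, concordance evaluation, and a downstream
treatment-timepoint classification experiment.

MTI assays such as t-CyCIF quantify a few dozen proteins per cell in situ,
but panels are small and markers fail (tissue loss, probe failure).
`mtimpute` is for analysts of MCMICRO-style single-cell quantification
tables who want to (a) infer a missing or failed marker per cell from the
rest of the panel, and (b) know whether the inferred values are good enough
to trust downstream.

## What it computes

Given a scaled feature table with cells *i* and panel proteins *p*, an
imputer predicts a withheld target *t* from the remaining intensities
x<sub>i,p≠t</sub>, optionally augmented with neighborhood features
n̄<sub>i,p</sub> — the mean of x<sub>j,p</sub> over all cells *j* of the
same biopsy within radius *r* ∈ {15, 30, 60, 90, 120} µm of cell *i*
(zero-filled when there are no neighbors). Four families:

* **null** — the training mean of the target (baseline);
* **elastic net** — linear model with L1/L2 penalty chosen by internal CV;
* **LightGBM** — gradient-boosted regression trees;
* **autoencoder** — a 2P→16→8→16→P encoder–decoder; targets are
  initialised at the train mean, then refined over 10 encode–decode
  cycles, the final estimate being the per-cell mean of the last 5
  iterations. One autoencoder imputes single proteins or whole staining
  rounds.

Evaluation is **patient-wise leave-one-out**: all biopsies of the held-out
patient form the test set, and scaling, spatial features, and model fitting
happen strictly on the training side. Errors are MAE/RMSE on the [0,1]
scale plus per-cell Pearson r; model pairs are compared with two-sided
Mann-Whitney U tests, Benjamini-Hochberg adjusted. Downstream checks
measure cluster agreement (ARI/AMI/silhouette), gated-phenotype agreement
(macro-Jaccard), and whether a pre- vs post-treatment cell classifier works
as well with imputed values as with ground truth.

Because real cohorts of this design are access-restricted, the package
includes a synthetic cohort generator (`mtimpute.synthetic`) that produces
4-patient pre/post cohorts with spatially autocorrelated niches, known
protein–protein dependencies, designated high-noise markers, a
neighborhood-driven marker, and a known treatment effect — every benchmark
property is testable against this known ground truth.

## Worked example

```python
import mtimpute as mt

# a 4-patient pre/post cohort, 16-protein panel, known ground truth
table, truth = mt.generate_cohort(mt.preset_paperlike(seed=7, cells_per_biopsy=800))

splits = mt.make_splits(table, "across_patient")          # 4 LOOCV folds
specs = [
    mt.ImputerSpec("null", ("pRB",)),
    mt.ImputerSpec("boosted_trees", ("pRB",)),             # non-spatial
    mt.ImputerSpec("boosted_trees", ("eCadherin",), 30.0), # 30 µm neighbors
    mt.ImputerSpec("boosted_trees", ("eCadherin",), 0.0),  # spatial baseline
]
metrics = mt.run_benchmark(table, table.panel, specs, splits,
                           n_replicates=3, base_seed=1)
print(mt.summarize(metrics)[["family", "target", "radius", "mae"]])
```

```
          family     target  radius       mae
0  boosted_trees  eCadherin     0.0  0.077653
1  boosted_trees  eCadherin    30.0  0.048961
2  boosted_trees        pRB     0.0  0.055985
3           null        pRB     0.0  0.156633
```

pRB is generated as 0.5·Ki67 + 0.3·pERK + 0.2·EGFR plus noise, so the
boosted trees cut the null model's error (0.157) by almost two thirds
(0.056); eCadherin's expression depends on the local cell-type
neighborhood, and with 30 µm neighbor-mean features its MAE drops from
0.078 to 0.049 — the spatial-information benefit the benchmark is designed
to expose.

The same pipelines are scriptable from the shell:

```bash
mtimpute simulate  --seed 7 --out runs/sim
mtimpute benchmark --config bench.yaml --seed 1 --out runs/bench
mtimpute treatment --config treat.yaml --seed 1 --out runs/treat
```

Every output directory contains the resolved config and base seed needed to
regenerate it byte-for-byte.

## Layout

| module | contents |
|---|---|
| `mtimpute.panel` / `io` / `scaling` | marker panel, table container + CSV I/O, min-max scaling |
| `mtimpute.synthetic` | cohort generator and the paper-like preset |
| `mtimpute.spatial` | fixed-radius neighbors, neighbor-mean features |
| `mtimpute.models` | the four imputer families, iterative autoencoder loop |
| `mtimpute.benchmark` | LOOCV splits, metrics, replicated runs, rank tests |
| `mtimpute.concordance` | clustering/gating agreement (ARI, AMI, silhouette, Jaccard) |
| `mtimpute.treatment` | tile selection + cell classification variant experiment |
| `mtimpute.cli` | `mtimpute simulate|impute|benchmark|concordance|treatment` |

See `docs/methods.md` for model details, generator assumptions, and
numerical conventions.
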