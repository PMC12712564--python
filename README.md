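# ehrshift

Unsupervised characterization of **temporal dataset shifts** in electronic
health record (EHR) data, and statistical association of those shifts with
the interyear performance of predictive models.

Long-running clinical datasets drift: coding systems are replaced, case mix
changes, documentation practices evolve. A model trained on one era can
silently degrade on another. `ehrshift` is for biostatisticians and clinical
ML engineers who want to detect and localize such drift **before** committing
to a model — and to quantify, afterwards, whether the drift they found
explains where model performance changes.

## What it computes

For admission-level data batched by calendar year (features x = harmonized
diagnosis/procedure chapter indicators + demographics, outcome y =
in-hospital death):

* **Data temporal heatmaps (DTHs)** — per-year estimates of the marginal
  p(x), the class prior p(y), the class-conditionals p(x|y), and the Bayes
  posterior p(y|x) = p(x|y)p(y) / Σ_y' p(x|y')p(y'), separating covariate,
  prior, and concept shift.
* **IGT projections** — each year's estimated distribution becomes a point:
  pairwise dissimilarities D[i,j] = √JSD₂(Pᵢ, Pⱼ) (square-root Jensen–Shannon
  divergence, base 2) are embedded by classical multidimensional scaling.
  Temporal subgroups and abrupt changes appear as clusters and gaps. The
  multivariate view reduces the mixed feature table with a FAMD-style SVD and
  applies per-year kernel density estimation on the first 3 dimensions.
* **Interyear evaluation matrices** — one classifier per year (random forest
  or gradient boosting, stratified 56/24/20 splits, Youden-index thresholds),
  each evaluated on every year's held-out test set, for six metrics.
* **Association tests** — 2-cluster partitions of the data IGT and of each
  metric's performance embedding (complete-linkage/Manhattan hierarchical
  clustering and first/last-year-initialized k-means) are cross-tabulated
  over the year labels and tested with the two-sided Fisher exact test,
  with Benjamini–Hochberg FDR adjustment across metrics.

A synthetic cohort generator with controllable covariate / prior / concept
shifts and an ICD-9→ICD-10-style coding transition makes the whole pipeline
testable end-to-end without any credentialed data. See `docs/methods.md` for
the model details and design choices.

## Worked example

```python
from ehrshift.pipeline import RunConfig, run_study

config = RunConfig(outdir="demo_run", seed=1, scenario_kind="combined",
                   n_per_year=2000)
manifest = run_study(config)
for row in manifest["association"]:
    if row["method"] == "kmeans":
        print(f"{row['metric']:<10} p={row['p_raw']:.4f} "
              f"adj={row['p_adjusted']:.4f} table={row['table']}")
```

This simulates 12 years × 2000 admissions with an abrupt covariate+concept
shift at 2014, characterizes the shift, trains yearly mortality models, and
tests the association. Output from this exact run:

```
roc_auc    p=0.0022 adj=0.0065 table=[[6, 0], [0, 6]]
pr_auc     p=0.0022 adj=0.0065 table=[[6, 0], [0, 6]]
precision  p=0.0152 adj=0.0303 table=[[5, 1], [0, 6]]
recall     p=1.0000 adj=1.0000 table=[[5, 1], [5, 1]]
accuracy   p=0.4545 adj=0.5455 table=[[2, 4], [0, 6]]
macro_f1   p=0.4545 adj=0.5455 table=[[2, 4], [0, 6]]
```

Each row tests independence between the data-shift partition of the years
(here exactly 2008–2013 vs 2014–2019, recovering the planted changepoint)
and that metric's performance partition: a 2×2 table of the 12 years and its
exact p-value. Small p means the unsupervised data characterization
anticipated where that metric's interyear behavior changes; with only 12
yearly labels and rare outcomes, noisy thresholded metrics (e.g. recall) do
not reach significance in every replicate, which is why the package's own
validation works with replicate frequencies (below).

The written artifacts (`demo_run/`) include the per-year cohort files, DTH
matrices, IGT coordinate tables, one evaluation matrix CSV per metric, the
partitions, the association table, and a `manifest.json` with SHA-256 hashes
and the per-stage seed chain.

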