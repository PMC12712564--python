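# Methods

## Problem and approach

`ehrshift` studies *temporal dataset shift* in admission-level electronic
health record (EHR) data: changes over calendar time in the joint distribution
p(x, y) of features x (diagnosis/procedure chapter indicators, demographics)
and a rare binary outcome y (in-hospital death). Three canonical components
are distinguished:

* **covariate shift** — p(x) changes while p(y|x) is stable;
* **prior-probability shift** — p(y) changes;
* **concept shift** — p(y|x) changes.

The characterization is unsupervised and model-agnostic. Per-year
distributions are estimated and compared in two complementary ways:

1. **Data temporal heatmaps (DTHs).** For each variable, a value × year
   probability matrix: the marginal p(x), the class prior p(y), the
   class-conditionals p(x|y), and the Bayes posterior
   p(y|x) = p(x|y) p(y) / Σ_y' p(x|y') p(y'). Posterior cells with zero
   evidence are NaN rather than 0.
2. **IGT projections.** Each year's distribution becomes a point in a latent
   space: pairwise dissimilarities D[i, j] = sqrt(JSD₂(P_i, P_j)) (the square
   root of the Jensen–Shannon divergence, base 2 — a metric bounded by 1) are
   embedded with classical (Torgerson) multidimensional scaling. Trends,
   abrupt changes and temporal subgroups appear as geometry.

For the multivariate view, the mixed feature table is reduced with a
FAMD-style decomposition (numeric columns standardized; each categorical
column expanded to indicators divided by sqrt(level proportion) and centered;
SVD of the processed matrix). On numeric-only input this is exactly PCA on
the correlation matrix, which the tests exploit as an oracle. Per-year
Gaussian product-kernel densities on the first d = 3 dimensions, evaluated on
a shared grid, turn each year into a probability mass vector for the JSD/MDS
machinery. Class-conditional maps are mixed with per-year prior weights and
renormalized to give the concept-shift view.

The supervised side trains one classifier per yearly batch (random forest or
gradient boosting) on stratified 56/24/20 train/validation/test splits (an
80/20 test split, then 30% of the training side held out for validation). A
single hyperparameter configuration is shared across the series, chosen by
the mean same-year validation ROC-AUC over a grid; the default grids contain
the reference configurations (random forest 500 trees / depth 9, gradient
boosting 100 estimators / depth 2). Decision thresholds are selected by the
Youden index J = sensitivity + specificity − 1 on the most recent year's
validation predictions — by default per model (each model scored on that
validation set); a global-threshold mode exists behind a flag. Evaluating
every model on every year's test set yields a 12×12 matrix per metric
(ROC-AUC, PR-AUC, precision, recall, accuracy, macro-F1); cells whose test
year lacks a class are NaN, never 0.

Association between the two views is tested at the year level: the data IGT
and each metric's performance embedding (dissimilarity
D[i, j] = 1 − (M[i, j] + M[j, i]) / 2 by default; a Manhattan row+column
profile mode is available) are each partitioned into k = 2 temporal clusters,
cross-tabulated over the 12 year labels, and tested with the two-sided Fisher
exact test (probability-ordering rule, ties included); p-values are adjusted
across metrics with Benjamini–Hochberg. Clustering follows the study design:
complete-linkage agglomeration on Manhattan distances, plus k-means (Lloyd,
deterministic) initialized at the first and last years' coordinates. The
elbow rule (second difference of the within-cluster Manhattan dispersion
around cluster medians) is advisory only and never overrides a configured k.

## Synthetic cohort generator

No public admission-level cohort with exact years ships with the package, so
the generator is a first-class module that emulates the study conditions:

* 12 yearly batches (2008–2019), configurable size per year;
* outcome prevalence 0.0291 per year by default (rare in-hospital mortality);
* 24 clinical chapters (14 diagnosis, 10 procedure) with fixed baseline
  Bernoulli prevalences, plus age (truncated normal, mean 62, SD 17, clipped
  to ≥ 18 to mirror the adult inclusion criterion), gender and ethnicity;
* a changepoint at 2014 splitting the series into two 6-year coding eras,
  with an ICD-9-style numeric code dialect before and an ICD-10-style
  alphanumeric dialect after — the mapping file, not the raw codes, carries
  the chapter identity, so the harmonization path is genuinely exercised.

Outcomes follow a logistic model logit p(y=1|x) = b_t + β·x whose intercept
b_t is recalibrated each year by root finding so the realized marginal
prevalence matches the configured p(y) — the simplest generative model with a
well-defined, manipulable p(y|x). A consequence worth noting: in a
covariate-shift scenario the per-year prevalence calibration induces a small
compensating intercept change, so p(y|x) is held fixed only up to that
intercept; the chapter coefficients, which carry the concept, never move
unless a concept shift is requested.

Preset magnitudes are calibration knobs, not estimates of the real ICD
transition: the covariate preset moves five chapter prevalences by ±0.30
across the changepoint (mirroring the redistribution pattern of chapters such
as circulatory diseases and imaging procedures when a coding system is
replaced); the concept preset changes five chapter coefficients (including a
sign reversal); the prior preset steps prevalence from 0.0291 to 0.06. One
named `numpy` Generator seeded from the scenario drives all draws, so equal
scenarios produce byte-identical cohorts.

What the generator does **not** emulate: per-patient correlation across
admissions, within-year seasonality, gradual (non-abrupt) drift, code-level
semantics beyond the chapter, missing data, and the year-assignment
uncertainty of deidentified data. Passing tests therefore demonstrate that
the pipeline detects the kinds of shifts it injects at realistic sizes — not
that real EHR shifts of arbitrary structure would be detected.

## Numerical choices

* **DTH smoothing**: Laplace α = 0.5 (Jeffreys-style) by default so divergence
  computations never meet empty cells; α = 0 available and used where
  exactness matters (the total-probability identity holds exactly at α = 0).
* **Numeric binning**: equal-width, 20 bins over the pooled range.
* **KDE**: Gaussian product kernel, Scott's rule per dimension per year
  (recorded in the map); grid of 32 points/dim for d ≤ 2 and 16 for d = 3
  (4096 cells) spanning the pooled range ± 5%. The regular grid makes the
  product kernel separable, so densities are computed from per-dimension
  kernel matrices combined by tensor contraction — exactly equal to the
  direct evaluation (tested) but orders of magnitude cheaper.
* **MDS**: classical scaling, deterministic; negative eigenvalue mass is
  truncated at zero and reported as a diagnostic; axis signs fixed so the
  first batch has nonnegative coordinates.
* **Ties**: Youden threshold ties resolve to the smallest candidate;
  hyperparameter ties to the smaller model (fewer trees, then shallower);
  per-fit seeds derive from a stable hash of (seed, year, parameters) so grid
  search results are independent of execution order.
* **Cluster labels** are canonicalized by first appearance along the year
  axis; all association statistics are invariant to relabeling.
* **Seeds**: one master seed fans out to stage seeds through SHA-256, each
  below 2³¹.

## Validation studies and their sizes

The package validates itself with three simulation studies, sized to run on a
single CPU in minutes (sizes are package choices, declared here):

* **Changepoint recovery** — combined covariate+concept scenarios, 2000
  admissions/year, 20 replicates: the 2-cluster hierarchical partition of the
  data IGT must split the years exactly at the changepoint, and the interyear
  ROC-AUC matrix must show a positive within-period minus cross-period gap,
  each in ≥ 95% of replicates.
* **Null calibration** — no-shift scenarios, 1000 admissions/year, 200
  replicates, a 50-tree forest (model quality is irrelevant to calibration
  under exchangeability): the frequency of raw Fisher p ≤ .05 per metric must
  lie in (0.5%, 12%). The clustering family for this study was an open
  design choice: complete-linkage clustering of noisy 12-point embeddings
  often isolates singleton years, and a 1-vs-11 table cannot reach p ≤ .05
  (minimum 1/12 ≈ .083), which makes the exact test extremely conservative.
  The calibration is therefore measured over the pipeline's full reported
  output — both clustering families (hierarchical and k-means) — mirroring
  how the association tables are actually produced and read. Even so, for
  metrics whose interyear matrix is nearly constant under the null (accuracy
  above all: the majority-class accuracy ≈ 0.97 everywhere, so its
  dissimilarity matrix is near-uniform and the embedding near-degenerate) the
  rejection rate sits at or below the lower edge of the band; which metric
  touches the boundary varies with the seed stream. This is extreme
  conservatism of the exact test at 12 exchangeable labels, not inflation —
  no metric's rate approaches the upper bound.
* **Bayes consistency** — conditional/prior DTHs reproduce the marginal
  exactly at α = 0, and posterior class blocks sum to 1.

At these scaled-down sizes the per-year test sets contain only ~12 positive
cases, so thresholded metrics (recall, precision) are noisy and individual
metric associations are not expected to reach significance in every
replicate; the directional ROC-AUC gap and the data-side partition are the
robust signatures. With all six metrics and strong shifts, individual
replicates frequently — but not uniformly — yield p ≤ .05 across the board,
which is why the package's claims are framed as replicate frequencies rather
than single-run significance.

## Known limitations

* The Fisher test is restricted to 2×2 tables (k = 2 clusters); larger k
  raises an explicit error rather than silently approximating an r×c exact
  test.
* Classical MDS only; no SMACOF/nonmetric variants.
* The reduction is pluggable but only the FAMD-style decomposition ships; no
  UMAP/t-SNE integration.
* Year-level association has only 12 exchangeable units; its power is
  intrinsically limited, and the calibration study above quantifies exactly
  how conservative the exact test is at that resolution.
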