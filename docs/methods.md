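# Methods

## The model

A cohort's laboratory history is summarized as a **clinarray matrix**
`X` (rows = biomarkers, columns = patients): cell `(b, p)` is the median
of every measurement of test `b` for patient `p` across all visits.
Medians are robust to the occasional aberrant draw and ignore
temporality, exactly as a cross-sectional factor analysis requires.

The analysis assumes the linear latent-factor model

```
X = A S
```

where the rows of `S` (k × n_patients) are mutually independent,
non-Gaussian latent physiological factors and `A` (m × k) is the mixing
matrix whose column `c` holds the biomarker **loadings** of factor `c`.
Independent component analysis estimates an unmixing matrix `W` with
`Y = W X ≈ S`; if `W = A⁻¹` the reconstruction is exact.  ICA is
identifiable only up to permutation, sign and scale of the components,
which dictates how every recovery test in this package is scored
(optimal bipartite matching on absolute correlations; the Amari index
for whole-system error).

## Pipeline stages

1. **Aggregation** (`clinarray.build_clinarray`): per-(patient,
   biomarker) median over all visits; even-count medians are the
   midpoint of the central pair; row/column order follows first
   appearance in the record stream, so output is deterministic.
2. **Pruning** (`clinarray.prune`): two passes, run exactly once, in
   order — first drop patients with fewer than 10 distinct observed
   biomarkers (strict `<`), then drop biomarkers observed in fewer than
   50% of the *remaining* patients (inclusive `>=`: exactly half
   survives).  Biomarker removal can push a surviving patient back under
   the patient threshold; such patients are counted in the report rather
   than re-filtered, because iterating the filters to a fixed point is a
   different (and more destructive) procedure than the stated one.
3. **Imputation** (`preprocess.knn_impute`): K-nearest-neighbour
   imputation with K = 10 along the biomarker (variable) axis, the
   convention of expression-matrix KNN imputation.  Distance between two
   biomarker rows is the root-mean-square difference over co-observed
   patients (normalizing by the co-observation count so sparsity does
   not inflate distances); rows sharing fewer than `min_shared_columns`
   (default 3) patients are ineligible neighbours.  A missing cell takes
   the 1/distance-weighted mean of the K nearest eligible rows observed
   at that patient; exact duplicates (distance 0) take a plain mean; a
   cell with no eligible neighbour falls back to its row mean.  Observed
   cells are never touched.
4. **Standardization** (`preprocess.standardize`): each biomarker row is
   centred to mean 0 and scaled to unit variance using the population
   (divide-by-n) convention, so that the whitening step's covariance is
   exactly the correlation matrix.  The per-row means and scales are
   returned for exact inversion.
5. **Decomposition** (`ica.decompose`): eigendecomposition of the sample
   covariance, optional scree-based component count, whitening to the
   top-k subspace, then symmetric (parallel) fixed-point FastICA.
6. **Consensus** (`consensus`): an ensemble of decompositions from
   independent random initializations, and two significance rules over
   the pooled absolute loadings.

## FastICA details

* **Symmetric, not deflationary.**  All component vectors are updated in
  parallel and re-orthonormalized by symmetric decorrelation
  `W ← (W Wᵀ)^(−1/2) W` each iteration.  Deflation would impose an
  estimation order and accumulate error into later components, which
  would bias the cross-run comparisons the consensus stage performs.
* **Contrasts.**  `logcosh` (nonlinearity `tanh u`) is the default — the
  standard robust negentropy approximation; `cube` (`u³`, kurtosis) is
  exposed as an option and is what the bundled benchmarks use, because
  the synthetic sources are Laplace (excess kurtosis 3) and the cube
  fixed points are better conditioned there.
* **Convergence** is declared when every row satisfies
  `|1 − |⟨w_new, w_old⟩|| < tol` (default 1e-6) — a sign-invariant
  criterion, matching the sign indeterminacy of the model.
* **Stabilized fallback.**  When a whitened component is only weakly
  non-Gaussian (heavy noise admixture), the plain fixed-point iteration
  can enter a period-2 limit cycle around its fixed point, with either
  contrast, and no iteration budget escapes it.  After a fruitless plain
  phase of `max_iter` iterations the solver retries with damped steps
  (1/2, then 1/4), sign-aligning the update with the current iterate so
  the average cannot cancel.  Damping leaves the fixed points unchanged
  and breaks the cycles; with it, the cube contrast converged on every
  one of 120 benchmark datasets tried (20 initializations each).  One
  dataset in 120 remains where the tanh fixed point is genuinely
  marginal and the logcosh run is flagged non-converged — which is
  precisely the situation the ensemble's convergence bookkeeping exists
  to absorb.
* **Loadings are read from `Â = pinv(W)`**, whose columns live in
  biomarker space (with sources scaled to unit variance,
  `Â[b, c] = cov(X_b, Y_c)`).  Reading them from the rows of `W` was
  evaluated as an alternative and behaves strictly worse for consensus
  extraction; the choice is dimensional analysis, not convention: in
  `X = A S` with biomarker rows, it is `A` that is indexed by biomarker.

## Component count: the scree rule

The retained component count is placed at the elbow of the descending
eigenvalue curve of the standardized data's covariance.  The elbow is
located as the interior index with the maximum second difference
(acceleration) of the curve **on a log scale**, and the retained count
is that index minus one; ties resolve to the smallest count.  The log
scale matters: eigenvalue decay is multiplicative, and on a linear scale
a single dominant factor occasionally out-accelerates the true
signal/noise elbow (measured: 94/100 correct on 4-source data at the
linear scale vs 98–100/100 at the log scale, identical answers on all
hand-checked curves).  Exact zeros (rank deficiency) are floored at
1e-15 of the leading eigenvalue before taking logs.  With fewer than
three eigenvalues there is no interior point and all components are
retained, with a warning.

## The ensemble and the two consensus rules

Runs use seeds derived from a master seed through numpy's splittable
`SeedSequence` tree, logged per run, so any single run can be reproduced
in isolation.  The component count is estimated once, before the
ensemble — a per-run count would make "the same component" meaningless
across runs.  Non-converged runs are recorded, excluded from all
statistics, and an ensemble with a non-converged majority is an error.

* **Top-fraction rule.**  Pool every absolute loading (biomarker ×
  component × converged run); compute each biomarker's mean absolute
  loading across components and runs; select biomarkers whose mean
  reaches the `(1 − fraction)` quantile of the reference distribution.
  Two readings of "the distribution" are implemented: the pooled scores
  themselves (`threshold_basis="pooled"`, the default) and the
  distribution of the per-biomarker means (`"means"`).  The pooled
  reading has a structural quirk worth knowing: whenever the share of
  genuinely large loadings exceeds `fraction`, the pooled quantile sits
  *inside* the cluster of large values, and since a mean over k
  components is diluted by the off-factor loadings, no biomarker can
  reach it — the rule returns the empty set.  For planted-recovery
  benchmarks the `means` basis with `fraction` matched to the expected
  prevalence of factor-driven biomarkers (0.1 for 3 of 30) is the
  meaningful operating point, and is what the bundled benchmarks use.
* **Argmax-consistency rule.**  For every converged run and component,
  record the biomarker with that component's highest absolute loading
  (ties broken by row order, logged); select biomarkers that win at
  least one component in **every** converged run.  Strict universality:
  winning 499 runs out of 500 does not qualify.
* Both rules depend only on per-run *sets* of absolute loading columns,
  so they are exactly invariant to per-run component permutations and
  sign flips; the mean reduction sorts each run's component loadings
  before summing so even the floating-point sums are bit-identical
  under permutation.

## The synthetic cohort generator

The generator is the package's test instrument; it emulates the
statistical shape of hospital laboratory data, not its clinical content
(no real reference ranges, units, age effects or disease-specific
models).

* **Sources** are i.i.d. Laplace, exactly standardized per row.
  Non-Gaussianity is a model requirement, and the Laplace law is a
  deliberately simple super-Gaussian stand-in, not a claim about real
  lab-value distributions.
* **Mixing**: background entries standard normal.  Planted (factor-
  driven) biomarkers get a primary loading of magnitude `planted_gain`
  on a designated component (cycling) and cross-loadings of magnitude
  `planted_cross × planted_gain` on the others, signs random, magnitudes
  fixed.  Fixed magnitudes make detectability deterministic — a planted
  entry of `gain × |N(0,1)|` is too small to dominate its column in a
  double-digit percentage of draws.  The cross-loadings reflect how
  factor-driven laboratory measurements behave empirically (a systemic
  biomarker correlates with every systemic factor, not exactly one) and
  are what makes the planted set recoverable by the mean-loading rule:
  a biomarker concentrated on a single one of k components has mean
  absolute loading ≈ max/k after row standardization, which diffuse
  background rows always exceed — with cross-loadings at 0.4 the
  planted means clear the background except for a ~3–5% per-cohort tail
  in which one background row draws both a large and an unusually
  diffuse mixing vector.
* **Records**: latent cell = `(A S)[b, p]` + one observation-noise draw;
  each visit re-measures the cell with independent jitter; visit dates
  are weekly ordinal offsets (temporality is deliberately meaningless);
  cells go missing completely at random at the patient×biomarker level,
  matching the granularity at which pruning and imputation operate.
* **Defaults** (one cohort realization): 400 patients × 30 biomarkers,
  3 sources, 3 planted at gain 5 with cross 0.4, 5 visits with jitter
  sd 0.5, observation noise sd 4.0 (per-biomarker communalities ≈ 0.2 —
  most of a lab test's variance is idiosyncratic, as in real panels),
  10% missing cells.

## Benchmark scenarios (what the acceptance script runs)

* *Source recovery*: 5 sources, 30 biomarkers, 1000 patients, zero
  noise, k = 5 — matched |correlation| per source and the Amari error of
  `W · Ã` (where `Ã` is the true mixing re-scaled by the standardization
  row scales).
* *Planted consensus*: defaults but 4000 patients (the scale of the
  motivating study's full cohort), no missingness, single visit; 50-run
  ensemble, k = 3 explicit, cube contrast, top-fraction rule at
  `fraction = 0.1` on the `means` basis.  Both rules should return
  exactly the planted triple and agree; across 100 cohort seeds this
  holds ~95% of the time, the remainder being the mean-rule tail above.
* *Feasibility*: 500-run ensemble on the default 30 × 400 cohort —
  wall time and converged share.
* *Pruning fixture*: a hand-enumerated 12 × 6 matrix (one sparse
  patient, one sparse biomarker → 11 × 5) plus the two boundary
  conventions.
* *Imputation head-to-head*: 20 × 50 correlated matrices, 10% masked,
  KNN (K = 10) vs row-mean RMSE over 100 repetitions.
* *Scree accuracy*: 4 sources, 30 biomarkers, noise sd 0.05, over 100
  repetitions.

Problem sizes were chosen so the full suite and the acceptance script
each complete in seconds on a single CPU while keeping every scenario at
the scale its claim refers to.

## Numerical conventions and degenerate inputs

* Variance everywhere is the population convention (divide by n).
* Whitening refuses components beyond the numerical rank (eigenvalue
  below 1e-15 of the leading one); `fastica` refuses input whose
  covariance deviates from the identity by more than 1e-4.
* Even-count medians: arithmetic midpoint.  Imputation distance ties:
  stable sort, row order.  Argmax ties: row order, logged.  Scree ties:
  smallest count.
* Empty record lists, non-finite lab values (named offender), fully
  missing rows/columns, constant rows (named biomarker), empty matrices
  after pruning: all explicit errors, surfaced with the failing stage's
  name by the pipeline driver.

## What passing these tests does and does not show

The generator draws from the exact model class the pipeline assumes
(linear mixing, independent super-Gaussian factors, Gaussian noise,
MCAR missingness).  Passing therefore shows the machinery is correct
and the consensus rules behave as designed *under the model*; it says
nothing about whether real clinical laboratory data satisfy linearity,
independence, or missingness-at-random — on real data, significant-set
outputs should be read as hypotheses for clinical follow-up, not
detections.  The top-1%-style threshold, in particular, has no
calibrated false-positive interpretation; it is a ranking heuristic.
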