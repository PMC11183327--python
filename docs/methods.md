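# Methods

## Problem setting

Input is a cells × genes count matrix with one categorical cell-state label
per cell (at least two classes). The goal is a small gene panel that
predicts the label well, found by ranking genes with a univariate
importance score and then selecting the prefix length by cross-validated
classification accuracy (incremental feature selection, IFS).

## Preprocessing

- **Gene filter.** Genes whose total count over all cells is zero are
  removed; nothing else is filtered. The operation is idempotent and keeps
  gene order.
- **Normalization.** The method name "normalized read counts" admits many
  conventions; we adopt the de-facto scRNA-seq default: scale each cell to
  a common total (10,000 by default, configurable) and apply log(1+x).
  This preserves within-cell rank order; rank-based scores downstream are
  insensitive to the exact scale.
- **Split.** Train/test splitting is stratified per class with
  round(fraction × class size) training cells (clipped so both sides stay
  nonempty), driven by a single seeded generator. Classes with fewer than
  two cells are rejected. The realized per-class counts are recorded in a
  JSON manifest keyed by cell id, never by position.

## Gene importance scores

- **Mutual information (`mi`).** Plug-in estimate
  I(X;Y) = Σ p(x,y) log₂[p(x,y)/(p(x)p(y))] on the empirical joint table,
  in bits (base 2 throughout). Continuous expression is first discretized
  into equal-frequency bins — min(16, number of distinct values) by
  default; tied values always share a bin.
- **Normalized partition-maximized MI (`mic`, default).** For each gene,
  the expression axis is partitioned into k intervals, k = 2…max_x_bins
  (default 16), with cut points between sorted distinct values chosen to
  maximize I(binned x; label); each maximum is normalized by
  log₂ min(k, n_classes) and the largest normalized value is returned, so
  scores live in [0,1] and 1 means some interval partition of the gene
  separates the classes perfectly. Because the label is categorical, only
  the expression axis is ever partitioned (no 2-D grid is needed).

  *Exact DP.* Maximizing I is equivalent to minimizing the weighted
  conditional label entropy, which is additive over bins, so the optimal
  k-partition satisfies a standard interval-partition recursion
  DP[k][j] = max_i (DP[k−1][i] + G(i, j]) over candidate cut positions;
  the DP is exact, O(max_x_bins · m²) for m distinct values.

  *Candidate coarsening.* For long vectors (m > max_candidates, default
  128) the candidate cuts are first coarsened to ~128 equal-frequency block
  edges (tied values kept together). This bounds runtime at ~1 ms/gene at
  n ≈ 1,000 cells while changing scores only marginally (the loss is the
  freedom to fine-tune cuts within a block, worth ≲0.03 on the unit scale
  in our tests and monotone downward); small inputs are always exact.
  Scores are invariant to strictly monotone transforms of expression since
  cuts act on order statistics.
- **CV² (`cv2`).** Population variance over squared mean. Constant genes
  score 0; zero-mean genes are undefined (NaN) — both are removed by the
  positive-score filter.
- **PCA loadings (`pca`).** Per-gene importance
  Σ_c EVR_c · loading²(gene, c) over the first n_components (default 50,
  capped by rank): the standard explained-variance-weighted squared-loading
  convention. Scores sum to the total explained variance ratio.

Rankings drop scores ≤ 0, sort descending, and break ties by gene id
ascending, so a ranking is a pure function of (matrix, labels, params).

## Incremental feature selection

- **Schedule.** Subset sizes step by 10 up to 1,000, by 200 up to 5,000,
  and by 1,000 beyond, always ending at the ranking length. This covers
  the panel sizes at which marker sets in this field are typically
  reported while keeping the sweep affordable.
- **Cross-validation.** Stratified k-fold (default 5), shuffled once with
  the run seed and *reused across all subset sizes*, so differences along
  the curve reflect gene subsets only. Classes smaller than the fold count
  are rejected.
- **Classifiers.** KNN, RBF-SVM (probability-enabled), random forest and
  XGBoost, instantiated with library defaults plus a fixed seed; every
  hyperparameter override is recorded in the artifact provenance. The
  learners are consumed as external implementations — boosting itself is
  not re-derived here.
- **Selection.** The optimum maximizes mean fold accuracy; ties go to the
  smaller subset (parsimony). Accuracy is the only selection criterion;
  other metrics are reported but never drive selection.

## Evaluation

Per-class one-vs-rest TP/FP/FN/TN from the confusion matrix give
precision TP/(TP+FP), recall TP/(TP+FN) and F1 = 2PR/(P+R); multiclass
accuracy is the confusion-matrix trace over the total. Macro (unweighted
class mean) averaging is the primary summary because the target use case
has imbalanced classes; micro averages are emitted alongside. Zero
denominators yield 0 with a logged warning. One-vs-rest AUC is computed
from the Mann–Whitney rank statistic with midranks for ties (identical to
trapezoidal ROC integration); a class absent from the truth gets NaN and
is excluded from the macro AUC with a warning.

## Synthetic data

The generator emulates the *structure* of a droplet scRNA-seq experiment
with discrete cell types — not any particular tissue's biology: multiclass
labels, overdispersed counts, uneven sequencing depth, and a small set of
planted markers among many exchangeable background genes.

- Counts are Gamma–Poisson (negative binomial) with one shared dispersion
  (default 0.5), variance μ + 0.5 μ²; no zero-inflation component, which
  the CV² and MIC tests have not required.
- Each type owns `markers_per_type` disjoint marker genes whose mean is
  multiplied by 2^LFC (default LFC 2) in cells of that type; all other
  gene means equal `baseline_mean` (default 1).
- Library sizes are lognormal with a 25% coefficient of variation around
  `library_size_mean` (default n_genes × baseline_mean, i.e. unit average
  scaling); per-cell means are rescaled to that budget, so the realized
  within-type marker mean sits ~1–2% under 2^LFC × baseline.
- The reference simulation used throughout testing is 1,200 cells ×
  2,000 genes, 6 equiprobable types, 10 markers per type, LFC 2, seed 7 —
  the same shape (cells : classes : minority-marker structure) as the
  six-subpopulation spinal-cord dataset this package was designed around,
  scaled to desk size.

What passing on synthetic data shows — and what it does not: recovery and
accuracy results demonstrate the machinery (scores, DP, CV loop, metrics)
is correct and well-calibrated under an NB model with clean, disjoint
markers. Real tissues add correlated genes, continuous gradients between
states, batch effects and ambient contamination; ranking quality there
must be validated on real labels.

## Numerical and design choices

- All information quantities use log base 2 and are reported in bits.
- MI values are clipped at 0 (the plug-in estimate can go −ε by rounding);
  MIC is clipped to [0,1].
- Ties: ranking ties break by gene id; IFS accuracy ties break toward the
  smaller subset; tied expression values are inseparable by construction
  (they share a discretization bin and can never straddle a cut).
- Degenerate inputs: constant genes score 0 (mi/mic/cv2/pca) and are
  filtered; a constant ranking input yields an empty-ranking error rather
  than an arbitrary order; cells with zero total count are a hard error at
  normalization, named individually.
- The supervised target for `mi`/`mic` is always the cell-type label —
  gene-versus-label is the only pairing consistent with supervised
  subpopulation prediction.
- Determinism: a single integer seed fixes the simulator stream, the split
  permutation, fold shuffling and every stochastic learner; artifacts
  rerun with identical config are byte-identical (JSON keys sorted, no
  timestamps).
- Null calibration is asserted as: mean selected IFS accuracy over 20
  label-shuffled replicates within 3 standard errors of chance, with SE
  taken as √(0.25/n_cells) for a single accuracy estimated on n_cells.
  The selection step (max over the curve) biases the optimum upward by
  ~2 accuracy points at n = 400, which this envelope covers; a
  √20-shrunk SE of the replicate mean would be guaranteed to fail for any
  max-selected statistic and is therefore not the right yardstick.
- Test and acceptance runs use the reference simulation with an IFS
  schedule of 10–200 genes (10 evaluation points): panels beyond 200 genes
  add nothing when only 60 markers exist, and the prefix property makes
  coarser upper ranges exactly nested, not approximated.

## Known limitations

- The MIC here is a 1-D partition score against a categorical label; it is
  not the two-continuous-variable MINE family (no characteristic matrix,
  no B(n) grid bound, no TIC), and no claim is made that its scores match
  any particular published tool's values.
- Candidate coarsening makes per-gene MIC scores at n ≳ 128 distinct
  values approximate (monotone underestimates; exact DP is available via
  `max_candidates`).
- Equal-frequency discretization of heavily tied (sparse) genes can merge
  bins, lowering `mi` resolution; `mic` handles ties natively.
- No HDF5/loom input, no hyperparameter search, no plotting beyond the
  CSV artifacts a plotting tool would consume.
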