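# scmarkers

Marker-gene selection and cell-state classification for single-cell
RNA-seq count matrices.

Annotating the cells of an scRNA-seq experiment — e.g. the endothelial,
astrocyte, microglial, neuronal, oligodendrocyte and pericyte
subpopulations of an injured spinal cord — usually relies on a handful of
marker genes buried among tens of thousands of mostly uninformative ones.
`scmarkers` finds those markers and turns them into a classifier:

1. **Rank** every gene by how informative it is about the cell-type label.
   The primary score is a normalized, partition-maximized mutual
   information: for gene expression *x* and label *y*,

       MIC(x, y) = max over k-interval partitions of x of  I(x_binned; y) / log2 min(k, |classes|)

   where I(X;Y) = Σ p(x,y) log2 [p(x,y) / (p(x)p(y))] is the plug-in mutual
   information. The maximizing cut points are found exactly by dynamic
   programming over the order statistics of *x*. Plain equal-frequency-binned
   MI, the squared coefficient of variation CV² = Var(x)/E[x]², and
   explained-variance-weighted PCA loadings are available as alternative
   rankings. Genes scoring ≤ 0 are excluded.
2. **Incremental feature selection (IFS):** sweep growing prefixes of the
   ranking (sizes 10, 20, …, 1000, 1200, …, 5000, 6000, …), score each
   prefix with stratified 5-fold cross-validated accuracy of a classifier
   (KNN, SVM, random forest or XGBoost), and keep the smallest prefix with
   the best mean accuracy.
3. **Refit and report:** train the final model on the selected genes and
   report accuracy, per-class and macro precision/recall/F1, the confusion
   matrix, and one-vs-rest ROC AUC on held-out cells.

A negative-binomial simulator with planted, type-specific marker genes is
bundled so the whole pipeline can be exercised and validated without any
external download.

## Worked example

```python
from scmarkers import (
    SyntheticConfig, simulate, filter_genes, normalize_counts, rank_genes,
    stratified_split, SplitSpec, ClassifierSpec, run_ifs, fit_final,
    evaluate_predictions,
)

cfg = SyntheticConfig(n_cells=1200, n_genes=2000, n_types=6,
                      markers_per_type=10, log2_fold_change=2.0, seed=7)
X, y, markers = simulate(cfg)                 # counts + labels + true markers
Xn = normalize_counts(filter_genes(X))        # drop silent genes, depth-normalize
ranking = rank_genes(Xn, y, method="mic")     # genes sorted by informativeness

train, test = stratified_split(Xn, y, SplitSpec(0.7, True, seed=7))
clf = ClassifierSpec("xgboost", seed=7)
curve = run_ifs(Xn.subset_cells(train), y.subset(train), ranking, clf,
                n_folds=5, seed=7,
                schedule=[10, 20, 30, 40, 60, 80, 100, 120, 160, 200])
print(curve.optimal_k, round(curve.optimal_accuracy, 4))
# 200 0.975

model = fit_final(Xn.subset_cells(train), y.subset(train),
                  ranking.top(curve.optimal_k), clf)
report = evaluate_predictions(y.subset(test).labels,
                              model.predict(Xn.subset_cells(test)),
                              model.classes,
                              proba=model.predict_proba(Xn.subset_cells(test)))
print(round(report.accuracy, 4), round(report.f1_macro, 4),
      round(report.auc_macro, 4))
# 0.9721 0.9718 0.9997
```

All 60 planted markers appear in the top 120 of the MIC ranking;
cross-validation then settles on a 200-gene panel whose held-out accuracy
is 0.972 with macro F1 0.972 and macro one-vs-rest AUC 0.9997.

The same pipeline is available from the shell, one subcommand per stage:

```bash
scmarkers simulate --out fx --seed 7
scmarkers split    --fixture fx --out split.json --seed 7
scmarkers rank     --fixture fx --split-manifest split.json --out ranking.csv
scmarkers ifs      --fixture fx --ranking ranking.csv --split-manifest split.json \
                   --out-prefix ifs --classifier xgboost --seed 7
scmarkers train    --fixture fx --ranking ranking.csv --k 200 --out model --seed 7
scmarkers evaluate --fixture fx --model model --split-manifest split.json \
                   --out report.json
```

Every artifact carries a JSON provenance block (parameters, seeds, config
hash) sufficient to regenerate it bit-identically.

## Layout

| module | contents |
| --- | --- |
| `scmarkers.io` | `ExpressionMatrix`/`CellLabels`, Matrix-Market + CSV readers, gene filtering, normalization, stratified split |
| `scmarkers.ranking` | MI, MIC partition DP, CV², PCA scores; `rank_genes`; `GeneRanker` (sklearn transformer) |
| `scmarkers.ifs` | step schedule, cross-validated prefix sweep, final fit; `IFSClassifier` (sklearn classifier) |
| `scmarkers.metrics` | confusion matrix, precision/recall/F1, one-vs-rest AUC, report JSON |
| `scmarkers.simulate` | negative-binomial generator with planted markers, fixture writer |
| `scmarkers.cli` | `scmarkers` command-line pipeline |

`GeneRanker` and `IFSClassifier` follow scikit-learn conventions
(`get_params`/`set_params`, fitted attributes with trailing underscores)
and compose with sklearn pipelines and model selection.
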