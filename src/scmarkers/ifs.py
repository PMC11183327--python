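"""Incremental feature selection (IFS).

Given a gene ranking, evaluate a classifier on growing prefixes of the
ranked list — subset sizes drawn from a fixed step schedule — scoring each
prefix by stratified k-fold cross-validated accuracy, and select the prefix
size with the best mean accuracy (smallest size on ties).  Fold assignment
is seeded once per run and shared across all subset sizes so that curve
differences reflect the gene subsets only.

Four classifier families are supported through :class:`ClassifierSpec`:
k-nearest neighbours, RBF support-vector machine, random forest, and
gradient-boosted trees (XGBoost).  All are consumed as external
implementations with library defaults unless hyperparameters are given.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import StratificationError, ValidationError, VocabularyError
from .io import CellLabels, ExpressionMatrix
from .ranking import GeneRanking

__all__ = [
    "ClassifierSpec",
    "IFSCurve",
    "step_schedule",
    "cross_validated_accuracy",
    "run_ifs",
    "fit_final",
    "FittedModel",
    "IFSClassifier",
]

CLASSIFIER_NAMES = ("knn", "svm", "rf", "xgboost")


@dataclass
class ClassifierSpec:
    """One of the four supported learners plus hyperparameters and a seed."""

    name: str = "xgboost"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValidationError(
                f"classifier must be one of {CLASSIFIER_NAMES}, got {self.name!r}"
            )

    def build(self):
        """Instantiate an unfitted scikit-learn-API classifier."""
        hp = dict(self.hyperparameters)
        if self.name == "knn":
            return KNeighborsClassifier(**hp)
        if self.name == "svm":
            hp.setdefault("probability", True)
            return SVC(random_state=self.seed, **hp)
        if self.name == "rf":
            return RandomForestClassifier(random_state=self.seed, **hp)
        from xgboost import XGBClassifier

        hp.setdefault("n_jobs", 1)
        hp.setdefault("verbosity", 0)
        return XGBClassifier(random_state=self.seed, **hp)


def step_schedule(n_ranked: int) -> list[int]:
    """Default IFS subset sizes: step 10 up to 1,000, step 200 up to 5,000,
    step 1,000 beyond; always terminated at ``n_ranked``."""
    if n_ranked < 1:
        raise ValidationError("n_ranked must be >= 1")
    ks = list(range(10, min(n_ranked, 1000) + 1, 10))
    ks += list(range(1200, min(n_ranked, 5000) + 1, 200))
    ks += list(range(6000, n_ranked + 1, 1000))
    if not ks or ks[-1] != n_ranked:
        ks.append(n_ranked)
    return ks


def _make_folds(y_codes: np.ndarray, n_folds: int, seed: int):
    """Materialized stratified folds, reusable across subset sizes."""
    counts = np.bincount(y_codes)
    small = np.flatnonzero((counts > 0) & (counts < n_folds))
    if small.size:
        raise StratificationError(
            f"class index {small[0]} has {counts[small[0]]} member(s); "
            f"need >= {n_folds} for {n_folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y_codes.size), y_codes))


def _fold_accuracies(values, y_codes, folds, clf_spec: ClassifierSpec) -> list[float]:
    accs = []
    for train_idx, test_idx in folds:
        model = clf_spec.build()
        model.fit(values[train_idx], y_codes[train_idx])
        accs.append(float(np.mean(model.predict(values[test_idx]) == y_codes[test_idx])))
    return accs


def cross_validated_accuracy(
    X: ExpressionMatrix,
    y: CellLabels,
    genes: list[str],
    clf: ClassifierSpec,
    n_folds: int = 5,
    seed: int = 0,
) -> list[float]:
    """Per-fold held-out accuracy of *clf* trained on the given gene subset."""
    y = y.aligned_to(X)
    cols = X.gene_index(genes)
    folds = _make_folds(y.codes, n_folds, seed)
    return _fold_accuracies(X.values[:, cols], y.codes, folds, clf)


@dataclass
class IFSCurve:
    """Cross-validated accuracy per subset size, with the optimum marked."""

    method: str
    classifier: ClassifierSpec
    points: list[tuple[int, list[float], float]]  # (k, fold accuracies, mean)
    optimal_k: int
    optimal_accuracy: float
    n_folds: int = 5
    seed: int = 0

    def to_df(self) -> pd.DataFrame:
        n_folds = len(self.points[0][1])
        rows = {
            "k": [k for k, _, _ in self.points],
            **{
                f"fold_{i + 1}": [fa[i] for _, fa, _ in self.points]
                for i in range(n_folds)
            },
            "mean_accuracy": [m for _, _, m in self.points],
        }
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_df().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "method": self.method,
            "classifier": self.classifier.name,
            "classifier_seed": self.classifier.seed,
            "hyperparameters": self.classifier.hyperparameters,
            "n_folds": self.n_folds,
            "cv_seed": self.seed,
            "optimal_k": self.optimal_k,
            "optimal_accuracy": self.optimal_accuracy,
        }


def run_ifs(
    X: ExpressionMatrix,
    y: CellLabels,
    ranking: GeneRanking,
    clf: ClassifierSpec,
    n_folds: int = 5,
    seed: int = 0,
    schedule: list[int] | None = None,
) -> IFSCurve:
    """Sweep nested ranking prefixes and pick the best cross-validated size.

    The optimum maximizes mean fold accuracy; ties go to the smaller subset
    (parsimony).  ``schedule`` overrides the default step schedule; sizes
    beyond the ranking length are clipped out.
    """
    if len(ranking) == 0:
        raise ValidationError("ranking is empty")
    y = y.aligned_to(X)
    codes = y.codes
    if schedule is None:
        schedule = step_schedule(len(ranking))
    else:
        schedule = sorted({min(k, len(ranking)) for k in schedule})
    folds = _make_folds(codes, n_folds, seed)
    all_cols = X.gene_index(ranking.genes)
    points: list[tuple[int, list[float], float]] = []
    for k in schedule:
        accs = _fold_accuracies(X.values[:, all_cols[:k]], codes, folds, clf)
        points.append((k, accs, float(np.mean(accs))))
    best_k, _, best_acc = max(points, key=lambda p: (p[2], -p[0]))
    return IFSCurve(
        method=ranking.method,
        classifier=clf,
        points=points,
        optimal_k=best_k,
        optimal_accuracy=best_acc,
        n_folds=n_folds,
        seed=seed,
    )


class FittedModel:
    """A trained classifier bound to a gene vocabulary and class list.

    Exposes hard predictions and class probabilities for any matrix sharing
    the gene vocabulary, and serializes to a directory (joblib model +
    JSON sidecar naming the gene list and classes).
    """

    def __init__(self, model, genes: list[str], classes: np.ndarray, spec: ClassifierSpec):
        self.model = model
        self.genes = list(genes)
        self.classes = np.asarray(classes, dtype=object)
        self.spec = spec

    def _matrix(self, X: ExpressionMatrix) -> np.ndarray:
        cols = X.gene_index(self.genes)
        return X.values[:, cols]

    def predict(self, X: ExpressionMatrix) -> np.ndarray:
        codes = self.model.predict(self._matrix(X))
        return self.classes[np.asarray(codes, dtype=int)]

    def predict_proba(self, X: ExpressionMatrix) -> np.ndarray:
        return self.model.predict_proba(self._matrix(X))

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.model, directory / "model.joblib")
        sidecar = {
            "genes": self.genes,
            "classes": [str(c) for c in self.classes],
            "classifier": self.spec.name,
            "classifier_seed": self.spec.seed,
            "hyperparameters": self.spec.hyperparameters,
        }
        (directory / "model.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, directory) -> "FittedModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        model = joblib.load(directory / "model.joblib")
        spec = ClassifierSpec(
            sidecar["classifier"],
            sidecar.get("hyperparameters", {}),
            sidecar.get("classifier_seed", 0),
        )
        return cls(model, sidecar["genes"], np.array(sidecar["classes"], dtype=object), spec)


def fit_final(
    X_train: ExpressionMatrix,
    y_train: CellLabels,
    genes: list[str],
    clf: ClassifierSpec,
) -> FittedModel:
    """Train the chosen classifier on the full training set restricted to *genes*."""
    if not genes:
        raise ValidationError("gene list is empty")
    y_train = y_train.aligned_to(X_train)
    cols = X_train.gene_index(genes)  # raises VocabularyError on unknown gene
    model = clf.build()
    model.fit(X_train.values[:, cols], y_train.codes)
    return FittedModel(model, list(genes), y_train.classes, clf)


# ---------------------------------------------------------------------------
# scikit-learn estimator


class IFSClassifier(BaseEstimator, ClassifierMixin):
    """Marker-selection classifier: rank genes, sweep prefixes by CV, refit.

    ``fit`` (1) ranks features by the chosen importance score, (2) runs
    incremental feature selection over the ranking with cross-validated
    accuracy, and (3) refits the base classifier on the optimal prefix.
    ``predict``/``predict_proba`` then use only the selected features.

    Parameters
    ----------
    ranking_method : {"mic", "mi", "cv2", "pca"}
    classifier : {"knn", "svm", "rf", "xgboost"}
    classifier_params : dict or None
        Hyperparameter overrides for the base learner.
    ranker_params : dict or None
        Extra keyword arguments for the ranking score.
    n_folds : int
        Stratified CV folds for the IFS sweep.
    seed : int
        Seeds both fold shuffling and any stochastic learner.
    schedule : list of int or None
        Subset sizes to evaluate (None = default step schedule).

    Attributes
    ----------
    ranking_ : GeneRanking
    ifs_curve_ : IFSCurve
    optimal_k_ : int
    optimal_accuracy_ : float
    selected_genes_ : list of str
    classes_ : ndarray
    estimator_ : fitted base classifier
    """

    def __init__(
        self,
        ranking_method: str = "mic",
        classifier: str = "xgboost",
        classifier_params: dict | None = None,
        ranker_params: dict | None = None,
        n_folds: int = 5,
        seed: int = 0,
        schedule: list[int] | None = None,
    ):
        self.ranking_method = ranking_method
        self.classifier = classifier
        self.classifier_params = classifier_params
        self.ranker_params = ranker_params
        self.n_folds = n_folds
        self.seed = seed
        self.schedule = schedule

    def _to_em(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix(
                X.to_numpy(dtype=float),
                X.index.astype(str).to_numpy(dtype=object),
                X.columns.astype(str).to_numpy(dtype=object),
            )
        X = np.asarray(X, dtype=float)
        return ExpressionMatrix(
            X,
            [f"c{i}" for i in range(X.shape[0])],
            [f"g{j}" for j in range(X.shape[1])],
        )

    def fit(self, X, y):
        from .ranking import rank_genes

        em = self._to_em(X)
        y = np.asarray(y)
        labels = CellLabels(em.cell_ids, y.astype(object))
        spec = ClassifierSpec(
            self.classifier, dict(self.classifier_params or {}), seed=self.seed
        )
        self.ranking_ = rank_genes(
            em, labels, method=self.ranking_method, **(self.ranker_params or {})
        )
        self.ifs_curve_ = run_ifs(
            em,
            labels,
            self.ranking_,
            spec,
            n_folds=self.n_folds,
            seed=self.seed,
            schedule=self.schedule,
        )
        self.optimal_k_ = self.ifs_curve_.optimal_k
        self.optimal_accuracy_ = self.ifs_curve_.optimal_accuracy
        self.selected_genes_ = self.ranking_.top(self.optimal_k_)
        fitted = fit_final(em, labels, self.selected_genes_, spec)
        self.model_ = fitted
        self.estimator_ = fitted.model
        self.classes_ = fitted.classes
        self.n_features_in_ = em.n_genes
        self.feature_names_in_ = em.gene_ids
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(self._to_em(X))

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._to_em(X))
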