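"""Gene ranking by class-informativeness and dispersion.

Four per-gene importance scores are provided:

``mi``
    Plug-in mutual information I(X;Y) (bits) between the gene's expression,
    discretized by equal-frequency binning, and the cell-type label.
``mic``
    A normalized, partition-maximized mutual information: the gene's
    expression axis is cut into k intervals (k = 2..max_x_bins), the cuts
    chosen by dynamic programming to maximize I(binned expression; label),
    and the maximum is normalized by log2 min(k, n_classes) so the score
    lies in [0, 1].  Because cuts act on order statistics the score is
    invariant to strictly monotone transforms of the expression values.
``cv2``
    Squared coefficient of variation, variance / mean^2 (population variance),
    the classic unsupervised dispersion score for highly variable genes.
``pca``
    Explained-variance-weighted squared PCA loadings summed over components —
    a standard loading-importance convention.

Genes scoring <= 0 are dropped; survivors are ranked by score descending
with ties broken by gene id.  :class:`GeneRanker` wraps the same scores as a
scikit-learn transformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .errors import EmptyResultError, ValidationError
from .io import CellLabels, ExpressionMatrix

__all__ = [
    "mutual_information",
    "discretize",
    "mic_score",
    "cv2_score",
    "pca_gene_scores",
    "rank_genes",
    "GeneRanking",
    "GeneRanker",
]

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# mutual information


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Plug-in mutual information between two discrete sequences, in bits.

    I(X;Y) = sum_{x,y} p(x,y) log2[ p(x,y) / (p(x) p(y)) ], estimated from
    the empirical joint distribution.  Non-negative and symmetric.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    # sum n_xy * log(n * n_xy / (n_x n_y)) / (n ln 2); xlogy handles zeros
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = n * joint / (px * py)
        terms = xlogy(joint, np.where(joint > 0, ratio, 1.0))
    return float(max(terms.sum() / (n * _LN2), 0.0))


def discretize(
    x: Sequence[float], n_bins: int, strategy: str = "equal_frequency"
) -> np.ndarray:
    """Bin a real sequence into integer codes 0..n_bins-1.

    ``equal_frequency`` assigns bins by rank so bin sizes differ by at most
    one when all values are distinct; tied values always share a bin.
    ``equal_width`` uses n_bins equal intervals spanning [min, max].
    Constant input collapses to a single bin.
    """
    x = np.asarray(x, dtype=float)
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    n = x.size
    if n == 0 or np.all(x == x[0]) or n_bins == 1:
        return np.zeros(n, dtype=int)
    if strategy == "equal_frequency":
        order = np.argsort(x, kind="stable")
        provisional = np.empty(n, dtype=int)
        provisional[order] = np.arange(n) * n_bins // n
        # tied values take the bin of their first (smallest-rank) occurrence
        df = pd.Series(provisional).groupby(x).transform("min").to_numpy()
        # renumber to consecutive codes
        _, codes = np.unique(df, return_inverse=True)
        return codes.astype(int)
    if strategy == "equal_width":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
        codes = np.digitize(x, edges[1:-1], right=False)
        return codes.astype(int)
    raise ValidationError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# partition-maximized normalized MI (MIC-style, 1-D grid vs categorical label)


def _prefix_class_counts(x: np.ndarray, y_codes: np.ndarray, n_classes: int):
    """Sort by x, group tied values, and return group boundaries + prefix counts.

    Returns (bounds, prefix) where bounds[j] is the number of observations in
    the first j value-groups and prefix[j, c] the count of class c among them.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y_codes[order]
    change = np.flatnonzero(np.diff(xs) != 0) + 1
    bounds = np.concatenate(([0], change, [xs.size]))
    onehot = np.zeros((xs.size + 1, n_classes))
    onehot[np.arange(1, xs.size + 1), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    return bounds, cum[bounds]


def _merge_candidates(bounds: np.ndarray, max_candidates: int) -> np.ndarray:
    """Coarsen cut candidates to ~max_candidates equal-frequency block edges."""
    n = bounds[-1]
    inner = bounds[1:-1]
    targets = np.round(np.arange(1, max_candidates) * n / max_candidates)
    pos = inner[np.searchsorted(inner, targets).clip(max=inner.size - 1)]
    # snap each target to the nearest admissible boundary
    lo = inner[(np.searchsorted(inner, targets) - 1).clip(min=0)]
    pick = np.where(np.abs(lo - targets) <= np.abs(pos - targets), lo, pos)
    return np.unique(np.concatenate(([0], pick, [n])))


def mic_score(
    x: Sequence[float],
    y: Sequence,
    max_x_bins: int = 16,
    max_candidates: int = 128,
) -> float:
    """Normalized partition-maximized mutual information in [0, 1].

    Maximizes the plug-in I(binned x; y) over all partitions of x into
    k = 2..max_x_bins intervals (cut points between sorted distinct values,
    found exactly by dynamic programming), each normalized by
    log2 min(k, n_classes); returns the largest normalized value.

    When x has more than ``max_candidates`` distinct values the candidate
    cuts are coarsened to ~max_candidates equal-frequency block edges before
    the DP, trading exactness for speed on long expression vectors; small
    inputs are always handled exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    classes, y_codes = np.unique(y, return_inverse=True)
    k_y = classes.size
    if k_y < 2:
        raise ValidationError("y must have at least 2 classes")
    if x.size < 4:
        raise ValidationError("need at least 4 observations")
    if max_x_bins < 2:
        raise ValidationError("max_x_bins must be >= 2")
    bounds, prefix = _prefix_class_counts(x, y_codes, k_y)
    if bounds.size - 1 < 2:  # fewer than 2 distinct values
        return 0.0
    if bounds.size - 1 > max_candidates:
        keep = _merge_candidates(bounds, max_candidates)
        sel = np.searchsorted(bounds, keep)
        bounds, prefix = keep, prefix[sel]
    return _mic_dp(bounds, prefix, max_x_bins, k_y)


def _mic_dp(bounds: np.ndarray, prefix: np.ndarray, max_x_bins: int, k_y: int) -> float:
    """Exact DP over interval partitions given prefix class counts at boundaries."""
    m = bounds.size - 1  # number of candidate blocks
    n = float(bounds[-1])
    totals = prefix[-1]
    h_y = float(xlogy(totals, totals).sum() - n * np.log(n)) / (-n * _LN2)
    # gain of a bin spanning boundaries (i, j]:
    #   G(i,j) = sum_c n_c log2 n_c - n_bin log2 n_bin   (so I = H(Y) + sum G / n)
    counts = np.clip(prefix[None, :, :] - prefix[:, None, :], 0, None)  # (i, j, class)
    n_bin = counts.sum(axis=2)
    gain = (xlogy(counts, counts).sum(axis=2) - xlogy(n_bin, n_bin)) / _LN2
    i_idx, j_idx = np.indices(gain.shape)
    gain[i_idx >= j_idx] = -np.inf  # only bins spanning i < j are admissible

    best = 0.0
    dp = gain[0].copy()  # exactly 1 bin ending at boundary j
    for k in range(2, min(max_x_bins, m) + 1):
        dp = np.max(dp[:, None] + gain, axis=0)
        if not np.isfinite(dp[m]):
            break
        i_k = h_y + dp[m] / n
        norm = np.log2(min(k, k_y))
        best = max(best, i_k / norm)
    return float(min(max(best, 0.0), 1.0))


def mic_score_exhaustive(
    x: Sequence[float], y: Sequence, max_x_bins: int = 4
) -> float:
    """Brute-force reference for :func:`mic_score`: enumerate every interval
    partition of x into 2..max_x_bins bins.  Exponential; tiny inputs only."""
    from itertools import combinations

    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    k_y = classes.size
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    change = np.flatnonzero(np.diff(xs) != 0) + 1
    if change.size == 0:
        return 0.0
    best = 0.0
    for k in range(2, max_x_bins + 1):
        for cuts in combinations(change.tolist(), k - 1):
            codes = np.searchsorted(np.array(cuts), np.arange(xs.size), side="right")
            i_k = mutual_information(codes, ys)
            best = max(best, i_k / np.log2(min(k, k_y)))
    return float(min(best, 1.0))


# ---------------------------------------------------------------------------
# unsupervised scores


def cv2_score(x: Sequence[float]) -> float:
    """Squared coefficient of variation: population variance / mean^2.

    Returns NaN when the mean is zero (gene marked for exclusion downstream).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    mean = x.mean()
    if mean == 0:
        return float("nan")
    return float(x.var() / mean**2)


def pca_gene_scores(X: ExpressionMatrix, n_components: int = 50) -> np.ndarray:
    """Per-gene importance from PCA: sum over components of
    explained-variance-ratio x squared loading.

    Scores are non-negative and sum across genes to the total explained
    variance ratio; zero-variance genes score 0.
    """
    return _score_matrix(X.values, None, "pca", n_components=n_components)


# ---------------------------------------------------------------------------
# ranking


@dataclass
class GeneRanking:
    """Ordered genes with strictly positive importance scores."""

    method: str
    entries: list[tuple[str, float]]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s <= 0 for _, s in self.entries):
            raise ValidationError("ranking scores must be strictly positive")
        genes = [g for g, _ in self.entries]
        if len(genes) != len(set(genes)):
            raise ValidationError("duplicate genes in ranking")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def top(self, k: int) -> list[str]:
        return self.genes[:k]

    def to_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "gene_id": [g for g, _ in self.entries],
                "score": [s for _, s in self.entries],
                "method": self.method,
            }
        )

    def to_csv(self, path) -> None:
        self.to_df().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GeneRanking":
        df = pd.read_csv(path, dtype={"gene_id": str})
        method = str(df["method"].iloc[0]) if len(df) else "unknown"
        return cls(method, list(zip(df["gene_id"], df["score"].astype(float))))


def _score_matrix(
    values: np.ndarray,
    y_codes: np.ndarray | None,
    method: str,
    *,
    n_bins: int = 16,
    max_x_bins: int = 16,
    max_candidates: int = 128,
    n_components: int = 50,
) -> np.ndarray:
    """Per-column importance scores for a cells x genes array."""
    n_cells, n_genes = values.shape
    if method in ("mi", "mic"):
        if y_codes is None:
            raise ValidationError(f"method {method!r} requires cell labels")
        k_y = int(y_codes.max()) + 1
        scores = np.empty(n_genes)
        if method == "mi":
            for j in range(n_genes):
                col = values[:, j]
                bins = min(n_bins, np.unique(col).size)
                scores[j] = mutual_information(
                    discretize(col, max(bins, 1)), y_codes
                )
        else:
            for j in range(n_genes):
                col = values[:, j]
                bounds, prefix = _prefix_class_counts(col, y_codes, k_y)
                if bounds.size - 1 < 2:
                    scores[j] = 0.0
                    continue
                if bounds.size - 1 > max_candidates:
                    keep = _merge_candidates(bounds, max_candidates)
                    sel = np.searchsorted(bounds, keep)
                    bounds, prefix = keep, prefix[sel]
                scores[j] = _mic_dp(bounds, prefix, max_x_bins, k_y)
        return scores
    if method == "cv2":
        means = values.mean(axis=0)
        var = values.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(means > 0, var / means**2, np.nan)
    if method == "pca":
        if n_components < 1:
            raise ValidationError("n_components must be >= 1")
        n_comp = min(n_components, n_cells - 1, n_genes)
        pca = PCA(n_components=n_comp, svd_solver="full")
        pca.fit(values)
        return pca.explained_variance_ratio_ @ pca.components_**2
    raise ValidationError(f"unknown ranking method {method!r}")


def rank_genes(
    X: ExpressionMatrix,
    y: CellLabels | None = None,
    method: str = "mic",
    **params,
) -> GeneRanking:
    """Score every gene, drop scores <= 0 (and NaN), and rank.

    Supervised methods (``mic``, ``mi``) require labels; ``cv2`` and ``pca``
    ignore them.  Ties are broken by gene id ascending so rankings are fully
    deterministic.
    """
    y_codes = None
    if method in ("mi", "mic"):
        if y is None:
            raise ValidationError(f"method {method!r} requires cell labels")
        y_codes = y.aligned_to(X).codes
    scores = _score_matrix(X.values, y_codes, method, **params)
    entries = [
        (str(g), float(s))
        for g, s in zip(X.gene_ids, scores)
        if np.isfinite(s) and s > 0
    ]
    if not entries:
        raise EmptyResultError("no gene scored above zero")
    entries.sort(key=lambda e: (-e[1], e[0]))
    return GeneRanking(method, entries, params={"method": method, **params})


# ---------------------------------------------------------------------------
# scikit-learn estimator


class GeneRanker(BaseEstimator, TransformerMixin):
    """Rank features by importance and select the top *k* as a transformer.

    Parameters
    ----------
    method : {"mic", "mi", "cv2", "pca"}
        Importance score; "mic"/"mi" are supervised and need ``y`` in fit.
    k : int or None
        Number of top-ranked features ``transform`` keeps (None = all that
        survive the positive-score filter).
    max_x_bins, max_candidates : int
        Partition-DP resolution for "mic".
    n_bins : int
        Equal-frequency bins for "mi".
    n_components : int
        PCA components for "pca".

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Raw importance score per input feature (NaN where undefined).
    ranking_ : GeneRanking
        Filtered, ordered ranking with feature names.
    feature_names_in_ : ndarray
        Column names (DataFrame input) or "g0".."gN-1".
    """

    def __init__(
        self,
        method: str = "mic",
        k: int | None = None,
        max_x_bins: int = 16,
        max_candidates: int = 128,
        n_bins: int = 16,
        n_components: int = 50,
    ):
        self.method = method
        self.k = k
        self.max_x_bins = max_x_bins
        self.max_candidates = max_candidates
        self.n_bins = n_bins
        self.n_components = n_components

    def _names(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X.columns.astype(str).to_numpy(dtype=object)
        return np.array([f"g{j}" for j in range(np.asarray(X).shape[1])], dtype=object)

    def fit(self, X, y=None):
        names = self._names(X)
        values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ValidationError("X must be 2-D")
        y_codes = None
        if self.method in ("mi", "mic"):
            if y is None:
                raise ValidationError(f"method {self.method!r} requires y")
            _, y_codes = np.unique(np.asarray(y), return_inverse=True)
        self.feature_names_in_ = names
        self.n_features_in_ = values.shape[1]
        self.scores_ = _score_matrix(
            values,
            y_codes,
            self.method,
            n_bins=self.n_bins,
            max_x_bins=self.max_x_bins,
            max_candidates=self.max_candidates,
            n_components=self.n_components,
        )
        entries = [
            (str(g), float(s))
            for g, s in zip(names, self.scores_)
            if np.isfinite(s) and s > 0
        ]
        if not entries:
            raise EmptyResultError("no feature scored above zero")
        entries.sort(key=lambda e: (-e[1], e[0]))
        self.ranking_ = GeneRanking(self.method, entries, params=self.get_params())
        return self

    def _selected_positions(self) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.feature_names_in_)}
        genes = self.ranking_.genes
        if self.k is not None:
            genes = genes[: self.k]
        return np.array([lookup[g] for g in genes], dtype=int)

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        pos = self._selected_positions()
        if isinstance(X, pd.DataFrame):
            return X.iloc[:, pos]
        return np.asarray(X)[:, pos]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "ranking_")
        return self.feature_names_in_[self._selected_positions()]
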