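"""Data model and I/O for labeled cell x gene expression matrices.

The in-memory convention is cells as rows and genes as columns, with string
identifiers for both axes.  On-disk formats are the Matrix Market triple used
by CellRanger-style pipelines (``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``,
stored genes x cells and transposed on read) and a dense CSV (header row =
gene ids, first column = cell ids).  Labels travel in a two-column CSV
(``cell_id,label``).

Also provides the standard preprocessing steps: dropping genes with zero
total count, library-size normalization with log1p, and a seeded stratified
train/test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, StratificationError, ValidationError, EmptyResultError

__all__ = [
    "ExpressionMatrix",
    "CellLabels",
    "SplitSpec",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "filter_genes",
    "normalize_counts",
    "stratified_split",
    "write_split_manifest",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        raise ValidationError(f"duplicate {what} ids")


@dataclass
class ExpressionMatrix:
    """Cells x genes numeric matrix with aligned identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_genes)
        Non-negative expression values (raw counts or normalized).
    cell_ids, gene_ids : sequences of unique strings.
    normalized : bool
        Whether library-size normalization + log1p has been applied.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def gene_index(self, gene_ids) -> np.ndarray:
        """Column positions of the given gene ids (order preserved)."""
        from .errors import VocabularyError

        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise VocabularyError(f"gene {exc.args[0]!r} not in matrix") from None

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        cols = self.gene_index(gene_ids)
        return ExpressionMatrix(
            self.values[:, cols],
            self.cell_ids,
            self.gene_ids[cols],
            normalized=self.normalized,
        )

    def subset_cells(self, indices) -> "ExpressionMatrix":
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[indices],
            self.cell_ids[indices],
            self.gene_ids,
            normalized=self.normalized,
        )


@dataclass
class CellLabels:
    """Categorical class per cell, aligned to an :class:`ExpressionMatrix`.

    ``classes`` is the ordered distinct label set (sorted lexicographically by
    default, for determinism); ``codes`` are integer positions into it.
    """

    cell_ids: np.ndarray
    labels: np.ndarray
    classes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("cell_ids and labels differ in length")
        _check_unique(self.cell_ids, "cell")
        if self.classes is None:
            self.classes = np.array(sorted(set(self.labels)), dtype=object)
        else:
            self.classes = np.asarray(self.classes, dtype=object)
            missing = set(self.labels) - set(self.classes)
            if missing:
                raise ValidationError(f"labels not in class list: {sorted(missing)}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def codes(self) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.classes)}
        return np.array([lookup[l] for l in self.labels], dtype=int)

    def aligned_to(self, X: ExpressionMatrix) -> "CellLabels":
        """Reorder labels to match the matrix's cell order."""
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            order = [lookup[c] for c in X.cell_ids]
        except KeyError as exc:
            raise ValidationError(f"cell {exc.args[0]!r} has no label") from None
        return CellLabels(self.cell_ids[order], self.labels[order], self.classes)

    def subset(self, indices) -> "CellLabels":
        indices = np.asarray(indices, dtype=int)
        return CellLabels(self.cell_ids[indices], self.labels[indices], self.classes)


@dataclass
class SplitSpec:
    """Train/test split specification: fraction in (0, 1), stratified flag, seed."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# readers / writers


def _read_id_column(path: Path) -> np.ndarray:
    """First column of a headerless TSV (CellRanger genes.tsv / barcodes.tsv)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def read_expression(path, format: str = "mtx_triple") -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``mtx_triple``: *path* is a directory with ``matrix.mtx``, ``genes.tsv``
    (or ``features.tsv``) and ``barcodes.tsv``; the matrix may be stored either
    genes x cells (CellRanger convention) or cells x genes — orientation is
    resolved from the sidecar lengths and normalized to cells-as-rows.

    ``dense_csv``: *path* is a CSV whose header row holds gene ids and whose
    first column holds cell ids.
    """
    path = Path(path)
    if format == "mtx_triple":
        mtx_path = path / "matrix.mtx"
        gene_path = path / "genes.tsv"
        if not gene_path.exists():
            gene_path = path / "features.tsv"
        cell_path = path / "barcodes.tsv"
        for p in (mtx_path, gene_path, cell_path):
            if not p.exists():
                raise FormatError(f"missing file: {p}")
        mat = scipy.io.mmread(mtx_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes = _read_id_column(gene_path)
        cells = _read_id_column(cell_path)
        n_r, n_c = mat.shape
        if (len(genes), len(cells)) == (n_r, n_c):
            mat = mat.T  # gene x cell triple -> cells as rows
        elif (len(cells), len(genes)) != (n_r, n_c):
            raise FormatError(
                f"sidecars ({len(genes)} genes, {len(cells)} cells) do not match "
                f"matrix shape {mat.shape}"
            )
        if np.any(mat < 0):
            raise ValidationError("matrix contains negative entries")
        return ExpressionMatrix(mat, cells, genes)
    if format == "dense_csv":
        if not Path(path).exists():
            raise FormatError(f"missing file: {path}")
        df = pd.read_csv(path, index_col=0)
        vals = df.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValidationError("matrix contains negative entries")
        return ExpressionMatrix(
            vals,
            df.index.astype(str).to_numpy(dtype=object),
            df.columns.astype(str).to_numpy(dtype=object),
        )
    raise ValidationError(f"unknown format {format!r}")


def write_expression(X: ExpressionMatrix, path, format: str = "mtx_triple") -> None:
    """Write a matrix in either on-disk layout (inverse of :func:`read_expression`)."""
    path = Path(path)
    if format == "mtx_triple":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.csr_matrix(X.values.T)  # stored genes x cells
        field = "integer" if np.all(X.values == np.round(X.values)) else "real"
        scipy.io.mmwrite(path / "matrix.mtx", sparse, field=field)
        pd.DataFrame({0: X.gene_ids, 1: X.gene_ids}).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.DataFrame({0: X.cell_ids}).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
    elif format == "dense_csv":
        X.to_df().to_csv(path, index_label="cell_id")
    else:
        raise ValidationError(f"unknown format {format!r}")


def read_labels(path) -> CellLabels:
    """Read a ``cell_id,label`` CSV."""
    df = pd.read_csv(path, dtype=str)
    if not {"cell_id", "label"} <= set(df.columns):
        raise FormatError("labels CSV must have columns cell_id,label")
    return CellLabels(df["cell_id"].to_numpy(object), df["label"].to_numpy(object))


def write_labels(y: CellLabels, path) -> None:
    pd.DataFrame({"cell_id": y.cell_ids, "label": y.labels}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing


def filter_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose total count across all cells is zero; keep gene order.

    Idempotent; raises :class:`EmptyResultError` if nothing survives.
    """
    totals = X.values.sum(axis=0)
    keep = totals > 0
    if not keep.any():
        raise EmptyResultError("all genes have zero total count")
    return ExpressionMatrix(
        X.values[:, keep], X.cell_ids, X.gene_ids[keep], normalized=X.normalized
    )


def normalize_counts(X: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization: scale each cell to total ``scale``, then log1p.

    The standard scRNA-seq depth correction; preserves within-cell rank order.
    """
    totals = X.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"cell {X.cell_ids[zero[0]]!r} has zero total count; cannot normalize"
        )
    vals = np.log1p(X.values * (scale / totals[:, None]))
    return ExpressionMatrix(vals, X.cell_ids, X.gene_ids, normalized=True)


def stratified_split(
    X: ExpressionMatrix, y: CellLabels, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test split.

    Per class, round(train_fraction x class size) cells (clipped so both sides
    stay nonempty) go to the training set.  Returns sorted integer index
    arrays; train and test are disjoint and jointly exhaustive.
    """
    y = y.aligned_to(X)
    codes = y.codes
    rng = np.random.default_rng(spec.seed)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    if spec.stratified:
        for c in range(y.n_classes):
            idx = np.flatnonzero(codes == c)
            if idx.size == 0:
                continue
            if idx.size < 2:
                raise StratificationError(
                    f"class {y.classes[c]!r} has {idx.size} cell(s); need >= 2"
                )
            perm = rng.permutation(idx)
            n_train = int(round(spec.train_fraction * idx.size))
            n_train = min(max(n_train, 1), idx.size - 1)
            train.append(perm[:n_train])
            test.append(perm[n_train:])
    else:
        perm = rng.permutation(X.n_cells)
        n_train = int(round(spec.train_fraction * X.n_cells))
        n_train = min(max(n_train, 1), X.n_cells - 1)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def write_split_manifest(
    path, X: ExpressionMatrix, y: CellLabels, spec: SplitSpec,
    train_idx: np.ndarray, test_idx: np.ndarray,
) -> None:
    """JSON manifest recording the realized split (seed, fraction, per-class counts, ids)."""
    y = y.aligned_to(X)
    codes = y.codes
    per_class = {
        str(cls): {
            "train": int(np.sum(codes[train_idx] == c)),
            "test": int(np.sum(codes[test_idx] == c)),
        }
        for c, cls in enumerate(y.classes)
    }
    manifest = {
        "seed": spec.seed,
        "train_fraction": spec.train_fraction,
        "stratified": spec.stratified,
        "per_class": per_class,
        "train_cell_ids": [str(c) for c in X.cell_ids[train_idx]],
        "test_cell_ids": [str(c) for c in X.cell_ids[test_idx]],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_split_manifest(path, X: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Recover train/test index arrays for *X* from a split manifest."""
    manifest = json.loads(Path(path).read_text())
    lookup = {c: i for i, c in enumerate(X.cell_ids)}
    try:
        train = np.array([lookup[c] for c in manifest["train_cell_ids"]], dtype=int)
        test = np.array([lookup[c] for c in manifest["test_cell_ids"]], dtype=int)
    except KeyError as exc:
        raise FormatError(f"manifest cell {exc.args[0]!r} not in matrix") from None
    return np.sort(train), np.sort(test)
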