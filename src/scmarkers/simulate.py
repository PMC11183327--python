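"""Synthetic labeled scRNA-seq count matrices with planted marker genes.

The generator emulates the structure of a droplet scRNA-seq experiment with
a handful of discrete cell types: overdispersed counts, uneven library
sizes, and a small set of genes upregulated in exactly one type each (the
planted markers), against a large background of uninformative genes.

Counts follow a Gamma-Poisson (negative-binomial) model with a single
shared dispersion: for gene g in cell c of type t the expected count is

    mu_gc = base_g(t) * L_c / sum_g base_g(t)

where base_g(t) is ``baseline_mean`` except for type t's markers, which are
multiplied by 2**log2_fold_change, and L_c is the cell's target library
size (``library_size_mean`` times a lognormal factor with 25% CV).  The
realized count is Poisson(Gamma(1/dispersion, mu * dispersion)), giving
variance mu + dispersion * mu^2.

Markers are disjoint across types so recovery scoring is unambiguous, and
every draw streams from one seeded generator, making datasets bit
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .io import CellLabels, ExpressionMatrix, write_expression, write_labels

__all__ = ["SyntheticConfig", "simulate", "write_fixture", "read_truth"]

# lognormal sigma giving a 25% coefficient of variation, mean 1
_LIBRARY_CV = 0.25
_LN_SIGMA = float(np.sqrt(np.log(1 + _LIBRARY_CV**2)))


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    ``library_size_mean=None`` defaults to ``n_genes * baseline_mean`` (unit
    average scaling), and ``class_proportions=None`` to balanced classes.
    """

    n_cells: int = 1200
    n_genes: int = 2000
    n_types: int = 6
    markers_per_type: int = 10
    log2_fold_change: float = 2.0
    baseline_mean: float = 1.0
    dispersion: float = 0.5
    library_size_mean: int | None = None
    class_proportions: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ValidationError("n_types * markers_per_type exceeds n_genes")
        if self.n_types < 2:
            raise ValidationError("need at least 2 cell types")
        if self.log2_fold_change < 0:
            raise ValidationError("log2_fold_change must be >= 0")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("baseline_mean and dispersion must be > 0")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if p.size != self.n_types or np.any(p <= 0) or abs(p.sum() - 1) > 1e-8:
                raise ValidationError(
                    "class_proportions must be n_types positive values summing to 1"
                )

    @property
    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            return np.full(self.n_types, 1.0 / self.n_types)
        return np.asarray(self.class_proportions, dtype=float)

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_genes": self.n_genes,
            "n_types": self.n_types,
            "markers_per_type": self.markers_per_type,
            "log2_fold_change": self.log2_fold_change,
            "baseline_mean": self.baseline_mean,
            "dispersion": self.dispersion,
            "library_size_mean": self.library_size_mean,
            "class_proportions": None
            if self.class_proportions is None
            else list(map(float, self.class_proportions)),
            "seed": self.seed,
        }


def simulate(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, CellLabels, dict[str, list[str]]]:
    """Draw a labeled count matrix; returns (matrix, labels, marker map).

    The marker map sends each type name (``type_0`` ...) to the gene ids
    planted as its markers (``gene_0000`` ...).
    """
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes, n_types = config.n_cells, config.n_genes, config.n_types

    gene_ids = np.array(
        [f"gene_{j:04d}" for j in range(n_genes)], dtype=object
    )
    cell_ids = np.array([f"cell_{i:04d}" for i in range(n_cells)], dtype=object)
    type_names = [f"type_{t}" for t in range(n_types)]

    types = rng.choice(n_types, size=n_cells, p=config.proportions)

    # disjoint marker blocks at the front of the gene list (ids, not positions,
    # are what recovery scoring uses, so placement is arbitrary)
    marker_map = {
        type_names[t]: gene_ids[
            t * config.markers_per_type : (t + 1) * config.markers_per_type
        ].tolist()
        for t in range(n_types)
    }

    base = np.full((n_types, n_genes), config.baseline_mean)
    fc = 2.0**config.log2_fold_change
    for t in range(n_types):
        cols = slice(t * config.markers_per_type, (t + 1) * config.markers_per_type)
        base[t, cols] *= fc

    lib_mean = (
        config.library_size_mean
        if config.library_size_mean is not None
        else n_genes * config.baseline_mean
    )
    lib = lib_mean * rng.lognormal(-_LN_SIGMA**2 / 2, _LN_SIGMA, size=n_cells)
    mu = base[types] * (lib / base[types].sum(axis=1))[:, None]

    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu * config.dispersion)
    counts = rng.poisson(lam).astype(float)

    X = ExpressionMatrix(counts, cell_ids, gene_ids)
    y = CellLabels(
        cell_ids,
        np.array([type_names[t] for t in types], dtype=object),
        classes=np.array(type_names, dtype=object),
    )
    return X, y, marker_map


def write_fixture(
    X: ExpressionMatrix,
    y: CellLabels,
    marker_map: dict[str, list[str]],
    directory,
    config: SyntheticConfig | None = None,
) -> Path:
    """Emit the full fixture layout: matrix.mtx + genes.tsv + barcodes.tsv +
    labels.csv + truth.json (+ config.yaml when the config is given)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression(X, directory, format="mtx_triple")
    write_labels(y, directory / "labels.csv")
    (directory / "truth.json").write_text(
        json.dumps(marker_map, indent=2, sort_keys=True)
    )
    if config is not None:
        (directory / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True)
        )
    return directory


def read_truth(directory) -> dict[str, list[str]]:
    return json.loads((Path(directory) / "truth.json").read_text())


def all_markers(marker_map: dict[str, list[str]]) -> list[str]:
    """Flattened, order-stable list of every planted marker gene."""
    out: list[str] = []
    for t in sorted(marker_map):
        out.extend(marker_map[t])
    return out
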