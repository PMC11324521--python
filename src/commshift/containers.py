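"""Core in-memory containers shared across the pipeline stages.

The package works on a cells x genes layout throughout. Raw counts live in a
:class:`CountMatrix` (sparse integer), normalized expression in a
:class:`NormalizedMatrix` (sparse float, with the per-cell size factors that
produced it). Per-cell annotation is a plain :class:`pandas.DataFrame` indexed
by cell id with columns ``cell_type``, ``condition``, ``sample`` and optionally
``pseudotime`` — see :func:`validate_annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

ANNOTATION_COLUMNS = ("cell_type", "condition", "sample")


def _as_csr(values) -> sp.csr_matrix:
    if sp.issparse(values):
        return values.tocsr()
    return sp.csr_matrix(np.asarray(values))


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} ids are not unique")
    return ids


@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, cells in rows, genes in columns."""

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_csr(self.values)
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cell ids x {len(self.gene_ids)} gene ids"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts contain negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise KeyError(f"cells not in matrix: {missing[:5]}")
        return np.array([lookup[c] for c in cells], dtype=int)

    def subset(self, cells=None, genes=None) -> "CountMatrix":
        rows = slice(None) if cells is None else self.cell_index(cells)
        cols = slice(None) if genes is None else self.gene_index(genes)
        vals = self.values[rows][:, cols]
        cid = self.cell_ids if cells is None else np.asarray(list(cells), dtype=object)
        gid = self.gene_ids if genes is None else np.asarray(list(genes), dtype=object)
        return CountMatrix(vals, cid, gid)


@dataclass
class NormalizedMatrix:
    """Depth-normalized expression (optionally log1p) with its size factors."""

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    size_factors: np.ndarray = field(default=None)  # type: ignore[assignment]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = _as_csr(self.values).astype(np.float64)
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        if self.size_factors is None:
            self.size_factors = np.ones(self.values.shape[0])
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match id vectors")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    gene_index = CountMatrix.gene_index
    cell_index = CountMatrix.cell_index

    def dense(self, genes=None) -> np.ndarray:
        """Dense cells x genes block (all genes, or the listed subset)."""
        if genes is None:
            return np.asarray(self.values.todense())
        cols = self.gene_index(genes)
        return np.asarray(self.values[:, cols].todense())


def validate_annotation(ann: pd.DataFrame, cm: CountMatrix | NormalizedMatrix,
                        require_pseudotime: bool = False) -> pd.DataFrame:
    """Check an annotation table against a matrix and return it aligned to cell order."""
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            raise ValueError(f"annotation is missing required column {col!r}")
    if require_pseudotime and "pseudotime" not in ann.columns:
        raise ValueError("annotation is missing required column 'pseudotime'")
    missing = [c for c in cm.cell_ids if c not in ann.index]
    if missing:
        raise ValueError(f"{len(missing)} cells missing from annotation, e.g. {missing[:3]}")
    return ann.loc[list(cm.cell_ids)]
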