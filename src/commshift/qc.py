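"""Barcode/gene quality control, depth normalization, HVG selection, scaling.

Barcode filtering follows the usual droplet QC recipe with one extra
statistic, *complexity* = log10(number of expressed genes) / log10(total
counts), which flags degenerate libraries whose reads pile into few genes.
All filters are evaluated once against the raw matrix (single pass, no
re-evaluation after removal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

METRICS_COLUMNS = ("total_counts", "n_features", "pct_mito", "pct_hemoglobin", "complexity")


@dataclass(frozen=True)
class QCThresholds:
    min_umis: int = 1000
    min_features: int = 800
    max_pct_mito: float = 15.0
    max_pct_hemoglobin: float = 5.0
    min_complexity: float = 0.8
    gene_min_counts: int = 10
    gene_min_barcodes: int = 10

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"QCThresholds.{name} must be >= 0")


def genes_by_prefix(gene_ids, prefix: str) -> set:
    """Gene ids starting with ``prefix`` (e.g. ``mt-`` for mitochondrial)."""
    return {g for g in gene_ids if str(g).startswith(prefix)}


def barcode_metrics(counts: CountMatrix, mito_genes=(), hemo_genes=()) -> pd.DataFrame:
    """Per-barcode QC metrics.

    Complexity is NaN (undefined) for barcodes with fewer than 2 total counts
    or no expressed gene; such barcodes always fail the complexity filter.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("cannot compute barcode metrics on an empty matrix")
    X = counts.values
    total = np.asarray(X.sum(axis=1)).ravel()
    n_feat = X.getnnz(axis=1)

    def _pct(gene_set, what):
        gene_set = set(gene_set)
        present = [g for g in counts.gene_ids if g in gene_set]
        missing = gene_set - set(present)
        if missing:
            warnings.warn(f"{what} genes not in matrix: {sorted(missing)[:5]}", stacklevel=3)
        if not present:
            return np.zeros(counts.n_cells)
        cols = counts.gene_index(present)
        subtotal = np.asarray(X[:, cols].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(total > 0, 100.0 * subtotal / total, 0.0)
        return pct

    with np.errstate(invalid="ignore", divide="ignore"):
        complexity = np.where(
            (total >= 2) & (n_feat >= 1),
            np.log10(np.maximum(n_feat, 1)) / np.log10(np.maximum(total, 2)),
            np.nan)
    return pd.DataFrame(
        {"total_counts": total.astype(int), "n_features": n_feat.astype(int),
         "pct_mito": _pct(mito_genes, "mitochondrial"),
         "pct_hemoglobin": _pct(hemo_genes, "hemoglobin"),
         "complexity": complexity},
        index=pd.Index(counts.cell_ids, name="cell_id"))


def filter_barcodes(metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> list:
    """Cell ids passing every barcode rule.

    Kept iff total >= min_umis AND n_features >= min_features AND
    pct_mito < max AND pct_hemoglobin < max AND complexity > min (strict;
    NaN complexity fails).
    """
    t = thresholds
    keep = (
        (metrics["total_counts"] >= t.min_umis)
        & (metrics["n_features"] >= t.min_features)
        & (metrics["pct_mito"] < t.max_pct_mito)
        & (metrics["pct_hemoglobin"] < t.max_pct_hemoglobin)
        & (metrics["complexity"] > t.min_complexity)  # NaN compares False
    )
    kept = list(metrics.index[keep])
    if not kept:
        logger.warning("no barcodes survive QC")
    return kept


def filter_genes(counts: CountMatrix, thresholds: QCThresholds = QCThresholds()) -> list:
    """Gene ids with >= gene_min_counts total counts in >= gene_min_barcodes barcodes."""
    if counts.n_cells == 0:
        raise ValueError("cannot filter genes of an empty matrix")
    total = np.asarray(counts.values.sum(axis=0)).ravel()
    n_bar = counts.values.getnnz(axis=0)
    keep = (total >= thresholds.gene_min_counts) & (n_bar >= thresholds.gene_min_barcodes)
    return list(np.asarray(counts.gene_ids)[keep])


def normalize(counts: CountMatrix, log1p: bool = False) -> NormalizedMatrix:
    """Median-library-size depth normalization.

    Size factor = total counts / median total counts; normalized value =
    raw / size factor, optionally log1p-transformed afterwards.
    """
    total = np.asarray(counts.values.sum(axis=1)).ravel()
    if np.any(total == 0):
        raise ValueError("barcode(s) with zero total counts; run barcode QC first")
    sf = total / np.median(total)
    X = sp.diags(1.0 / sf) @ counts.values.astype(np.float64)
    X = X.tocsr()
    if log1p:
        X.data = np.log1p(X.data)
    return NormalizedMatrix(X, counts.cell_ids, counts.gene_ids,
                            size_factors=sf, log_transformed=log1p)


def select_hvg(norm: NormalizedMatrix, n: int) -> list:
    """Top-``n`` highly variable genes by variance of log1p expression.

    Ties are broken lexicographically by gene id, so the selection is
    deterministic.
    """
    if n <= 0:
        raise ValueError("number of HVGs must be positive")
    if n > norm.n_genes:
        raise ValueError(f"requested {n} HVGs from {norm.n_genes} genes")
    X = norm.values.copy()
    if not norm.log_transformed:
        X.data = np.log1p(X.data)
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean ** 2
    order = sorted(range(norm.n_genes), key=lambda j: (-var[j], str(norm.gene_ids[j])))
    return [norm.gene_ids[j] for j in order[:n]]


def scale_capped(norm: NormalizedMatrix, genes=None, cap: float = 10.0):
    """Per-gene z-scaling (population sd) with an upper cap, no lower cap.

    Zero-variance genes map to all zeros. Returns ``(matrix, gene_ids)`` with
    the matrix dense cells x genes.
    """
    gene_ids = np.asarray(list(genes), dtype=object) if genes is not None else norm.gene_ids
    X = norm.dense(genes=list(gene_ids) if genes is not None else None)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return np.minimum(Z, cap), gene_ids
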