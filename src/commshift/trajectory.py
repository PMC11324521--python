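"""Pseudotime-binned gene-module detection.

Cells along a lineage are binned into ``n_bins`` (default 21) bins of equal
cell numbers; per-bin mean expression profiles are z-scaled per gene across
bins; gene-gene Pearson correlations above a threshold (default 0.5, strict)
form a weighted graph; and Leiden community detection (resolution 1) yields
the gene modules. Pseudotime itself is an input — trajectory inference is out
of scope — with a trivial marker-rank fallback for demos.
"""

from __future__ import annotations

import logging

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

from .containers import NormalizedMatrix

logger = logging.getLogger(__name__)

UNCLUSTERED = "unclustered"


def bin_pseudotime(pseudotime: pd.Series, n_bins: int = 21) -> pd.Series:
    """Equal-cell-number pseudotime bins; returns per-cell bin index.

    Cells are ordered by (pseudotime, cell id); with n = q * n_bins + r cells,
    the first r bins receive q + 1 cells.
    """
    pt = pseudotime.dropna()
    n = len(pt)
    if n < n_bins:
        raise ValueError(f"{n} cells with finite pseudotime < {n_bins} bins")
    order = sorted(pt.index, key=lambda c: (pt[c], str(c)))
    q, r = divmod(n, n_bins)
    sizes = [q + 1] * r + [q] * (n_bins - r)
    bins = np.repeat(np.arange(n_bins), sizes)
    return pd.Series(bins, index=pd.Index(order, name="cell_id"), name="bin")


def pseudotime_from_marker(norm: NormalizedMatrix, gene: str) -> pd.Series:
    """Fallback pseudotime: rank of a marker gene's expression, scaled to [0, 1]."""
    x = norm.dense(genes=[gene]).ravel()
    ranks = pd.Series(x, index=norm.cell_ids).rank(method="first") - 1
    return ranks / max(len(ranks) - 1, 1)


def bin_profiles(norm: NormalizedMatrix, bins: pd.Series, genes) -> pd.DataFrame:
    """Gene x bin matrix of per-bin means, z-scaled per gene across bins.

    Genes with zero variance across bins are dropped and listed in
    ``result.attrs['dropped_genes']``.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    cells = list(bins.index)
    X = norm.dense(genes=genes)[norm.cell_index(cells), :]
    b = bins.to_numpy()
    n_bins = int(b.max()) + 1
    profiles = np.empty((len(genes), n_bins))
    for k in range(n_bins):
        profiles[:, k] = X[b == k].mean(axis=0)
    mean = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    keep = (sd.ravel() > 0)
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        logger.info("dropped %d constant-profile genes", len(dropped))
    z = (profiles[keep] - mean[keep]) / sd[keep]
    out = pd.DataFrame(z, index=pd.Index([g for g, k in zip(genes, keep) if k], name="gene"),
                       columns=pd.RangeIndex(n_bins, name="bin"))
    out.attrs["dropped_genes"] = dropped
    return out


def correlation_graph(profiles: pd.DataFrame, r_min: float = 0.5) -> pd.DataFrame:
    """Undirected edges (gene_a, gene_b, weight) for pairs with Pearson r > r_min."""
    if len(profiles) < 2:
        raise ValueError("need at least two genes to build a correlation graph")
    R = np.corrcoef(profiles.to_numpy())
    iu, ju = np.triu_indices(len(R), k=1)
    mask = R[iu, ju] > r_min
    genes = profiles.index.to_numpy()
    return pd.DataFrame({"gene_a": genes[iu[mask]], "gene_b": genes[ju[mask]],
                         "weight": R[iu, ju][mask]})


def leiden_modules(edges: pd.DataFrame, genes, resolution: float = 1.0,
                   seed: int = 0) -> pd.Series:
    """Leiden partition (RB modularity) of the correlation graph.

    ``genes`` is the full node universe; genes without any edge are assigned
    the module :data:`UNCLUSTERED`. Module ids are ``"m<k>"`` ordered by
    decreasing module size. Deterministic for a fixed seed.
    """
    genes = list(genes)
    pos = {g: i for i, g in enumerate(genes)}
    if edges.empty:
        logger.warning("empty correlation graph; all genes unclustered")
        return pd.Series(UNCLUSTERED, index=pd.Index(genes, name="gene"), name="module")
    g = ig.Graph(n=len(genes),
                 edges=[(pos[a], pos[b]) for a, b in zip(edges["gene_a"], edges["gene_b"])])
    g.es["weight"] = list(edges["weight"])
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed)
    membership = np.asarray(part.membership)
    degree = np.asarray(g.degree())
    labels = np.empty(len(genes), dtype=object)
    cluster_sizes = pd.Series(membership[degree > 0]).value_counts()
    rename = {c: f"m{k}" for k, c in enumerate(cluster_sizes.index)}
    for i in range(len(genes)):
        labels[i] = rename.get(membership[i], UNCLUSTERED) if degree[i] > 0 else UNCLUSTERED
    return pd.Series(labels, index=pd.Index(genes, name="gene"), name="module")


def module_summaries(assignment: pd.Series, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-module per-bin mean z-profile with a 95% normal confidence band.

    CI = mean +- 1.96 * sd / sqrt(m) across the module's member genes
    (population sd, so a single-gene module gets a zero-width, flagged band).
    """
    rows = []
    for module, members in assignment.groupby(assignment):
        if module == UNCLUSTERED:
            continue
        sub = profiles.loc[profiles.index.intersection(members.index)]
        m = len(sub)
        mean = sub.mean(axis=0)
        half = 1.96 * sub.std(axis=0, ddof=0) / np.sqrt(m)
        for b in profiles.columns:
            rows.append({"module": module, "bin": int(b), "n_genes": m,
                         "mean": mean[b], "ci_lo": mean[b] - half[b],
                         "ci_hi": mean[b] + half[b], "degenerate": m == 1})
    return pd.DataFrame(rows)


def gene_bin_summaries(norm: NormalizedMatrix, bins: pd.Series, genes) -> pd.DataFrame:
    """Per-gene per-bin mean normalized expression with a 95% CI across cells."""
    genes = list(genes)
    cells = list(bins.index)
    X = norm.dense(genes=genes)[norm.cell_index(cells), :]
    b = bins.to_numpy()
    rows = []
    for k in range(int(b.max()) + 1):
        sub = X[b == k]
        m = len(sub)
        mean = sub.mean(axis=0)
        half = 1.96 * sub.std(axis=0, ddof=0) / np.sqrt(m)
        for j, g in enumerate(genes):
            rows.append({"gene": g, "bin": k, "n_cells": m, "mean": mean[j],
                         "ci_lo": mean[j] - half[j], "ci_hi": mean[j] + half[j]})
    return pd.DataFrame(rows)
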