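"""Pseudobulk differential expression and one-vs-many aggregation.

Counts are summed per (group, sample) into pseudobulk profiles and compared
with a negative-binomial Wald test: median-of-ratios size factors, gene-wise
method-of-moments dispersion (floored at 1e-8), a two-group log-link NB GLM
fitted by vectorized IRLS, and a two-sided normal p on LFC/SE with BH
adjustment. This is a plain NB Wald test without dispersion shrinkage or LFC
moderation; its guarantees are calibration and power properties, not
replication of any particular bulk DE tool's decimals.

One-vs-many comparisons (one group against each of several others) are
aggregated as the arithmetic mean log2FC, a Fisher combination of the
per-comparison adjusted p-values, and a count of comparisons whose log2FC
clears a threshold (default 2).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from .containers import CountMatrix, validate_annotation
from .stats import TINY, bh_adjust, fisher_combine

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)
_DISPERSION_FLOOR = 1e-8


def make_pseudobulk(counts: CountMatrix, ann: pd.DataFrame,
                    group_key: str = "cell_type", sample_key: str = "sample") -> pd.DataFrame:
    """Sum raw counts per (group, sample); rows MultiIndex (group, sample), columns genes."""
    ann = validate_annotation(ann, counts)
    idx = pd.MultiIndex.from_arrays([ann[group_key], ann[sample_key]],
                                    names=[group_key, sample_key])
    codes, uniques = pd.factorize(idx)
    onehot = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(len(uniques), len(codes)))
    summed = np.asarray((onehot @ counts.values).todense()).astype(np.int64)
    return pd.DataFrame(summed, index=pd.MultiIndex.from_tuples(uniques,
                                                                names=[group_key, sample_key]),
                        columns=counts.gene_ids)


def median_of_ratios(pb: pd.DataFrame) -> np.ndarray:
    """DESeq-style size factors: median over genes of counts / geometric mean."""
    K = pb.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logK = np.log(K)
    finite = np.all(np.isfinite(logK), axis=0)
    if not finite.any():
        raise ValueError("no gene has positive counts in every sample; cannot size-factor")
    log_gm = logK[:, finite].mean(axis=0)
    sf = np.exp(np.median(logK[:, finite] - log_gm, axis=1))
    return sf


def _mom_dispersion(K: np.ndarray, sf: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion alpha (Var = mu + alpha mu^2)."""
    y = K / sf[:, None]
    n, _ = K.shape
    qhat = np.empty_like(y)
    for g in np.unique(groups):
        m = groups == g
        qhat[m] = y[m].mean(axis=0)
    resid2 = (y - qhat) ** 2
    shot = qhat / sf[:, None]  # Poisson part of Var(K/s) = q/s + alpha q^2
    num = (resid2 - shot).sum(axis=0)
    den = (qhat ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den > 0, num / den, 0.0) * n / max(n - 2, 1)
    return np.maximum(alpha, _DISPERSION_FLOOR)


def _moderated_dispersion(K: np.ndarray, sf: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Gene-wise dispersion moderated by a parametric mean-dispersion trend.

    The per-gene method-of-moments estimate is noisy at pseudobulk sample
    sizes and underestimation inflates the Wald test; fitting the DESeq-style
    trend ``alpha(mu) = a0 + a1/mu`` across genes and taking the maximum of
    the gene-wise and trended values keeps the test calibrated while still
    tracking genuinely high-dispersion genes.
    """
    mom = _mom_dispersion(K, sf, groups)
    mu = (K / sf[:, None]).mean(axis=0)
    ok = (mom > 1e-6) & (mu > 0)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(int(ok.sum())), 1.0 / mu[ok]])
        coef = np.maximum(np.linalg.lstsq(A, mom[ok], rcond=None)[0], 0.0)
        with np.errstate(divide="ignore"):
            trend = np.where(mu > 0, coef[0] + coef[1] / np.maximum(mu, 1e-12),
                             _DISPERSION_FLOOR)
        trend = np.maximum(trend, _DISPERSION_FLOOR)
    else:  # too few genes for a trend; fall back to gene-wise values
        trend = np.full_like(mom, _DISPERSION_FLOOR)
    return np.maximum(mom, trend)


def _irls_two_group(K: np.ndarray, sf: np.ndarray, is_a: np.ndarray,
                    alpha: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Vectorized two-group NB GLM (log link, offset log sf) across genes.

    Returns ``(lfc_natural, se)`` for the group-A coefficient. Group means of
    zero are floored at half a count over the group's total size factor so the
    fit stays finite.
    """
    n, G = K.shape
    x = is_a.astype(float)
    offs = np.log(sf)
    qa = (K[is_a] / sf[is_a, None]).mean(axis=0)
    qb = (K[~is_a] / sf[~is_a, None]).mean(axis=0)
    floor_a = 0.5 / sf[is_a].sum()
    floor_b = 0.5 / sf[~is_a].sum()
    qa = np.maximum(qa, floor_a)
    qb = np.maximum(qb, floor_b)
    b0 = np.log(qb)
    b1 = np.log(qa) - np.log(qb)
    for _ in range(max_iter):
        eta = b0[None, :] + x[:, None] * b1[None, :] + offs[:, None]
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[None, :] * mu)
        z = (eta - offs[:, None]) + (K - mu) / mu
        s00 = W.sum(axis=0)
        s01 = (W * x[:, None]).sum(axis=0)
        s11 = (W * (x ** 2)[:, None]).sum(axis=0)
        t0 = (W * z).sum(axis=0)
        t1 = (W * z * x[:, None]).sum(axis=0)
        det = s00 * s11 - s01 ** 2
        det = np.where(det > 0, det, np.nan)
        nb0 = (s11 * t0 - s01 * t1) / det
        nb1 = (s00 * t1 - s01 * t0) / det
        step = np.nanmax(np.abs(nb1 - b1)) if G else 0.0
        bad = ~np.isfinite(nb0) | ~np.isfinite(nb1)
        nb0 = np.where(bad, b0, nb0)
        nb1 = np.where(bad, b1, nb1)
        b0, b1 = nb0, nb1
        if step < tol:
            break
    eta = b0[None, :] + x[:, None] * b1[None, :] + offs[:, None]
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[None, :] * mu)
    s00 = W.sum(axis=0)
    s01 = (W * x[:, None]).sum(axis=0)
    s11 = (W * (x ** 2)[:, None]).sum(axis=0)
    det = s00 * s11 - s01 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        var_b1 = np.where(det > 0, s00 / det, np.inf)
    return b1, np.sqrt(var_b1)


def nb_wald_test(pb: pd.DataFrame, group_a, group_b) -> pd.DataFrame:
    """NB Wald test of group A over group B on a pseudobulk matrix.

    Returns a per-gene frame with ``log2FC`` (A over B), ``p`` and ``p_adj``
    (BH over tested genes). Genes with zero counts in both groups are excluded
    and listed in ``result.attrs['excluded_genes']``.
    """
    group_level = pb.index.names[0]
    rows_a = pb.xs(group_a, level=group_level, drop_level=False)
    rows_b = pb.xs(group_b, level=group_level, drop_level=False)
    for name, rows in ((group_a, rows_a), (group_b, rows_b)):
        if len(rows) == 0:
            raise ValueError(f"group {name!r} has no pseudobulk samples")
        if len(rows) < 2:
            warnings.warn(f"group {name!r} has a single sample; inference is unreliable",
                          stacklevel=2)
    sub = pd.concat([rows_a, rows_b])
    K = sub.to_numpy(dtype=float)
    is_a = np.array([ix[0] == group_a for ix in sub.index])
    tested = K.sum(axis=0) > 0
    excluded = list(sub.columns[~tested])
    K = K[:, tested]
    sf = median_of_ratios(sub)
    groups = is_a.astype(int)
    alpha = _moderated_dispersion(K, sf, groups)
    lfc_nat, se = _irls_two_group(K, sf, is_a, alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se > 0, lfc_nat / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(wald))
    res = pd.DataFrame({"log2FC": lfc_nat / _LN2, "p": p, "p_adj": bh_adjust(p)},
                       index=pd.Index(sub.columns[tested], name="gene"))
    res.attrs["excluded_genes"] = excluded
    if excluded:
        logger.info("excluded %d all-zero genes from %s vs %s", len(excluded), group_a, group_b)
    return res


def frac_expressed(counts: CountMatrix, ann: pd.DataFrame, keys="cell_type") -> pd.DataFrame:
    """Fraction of cells with count > 0, per gene (rows) per group (columns).

    ``keys`` may be one annotation column or a list (columns become tuples).
    """
    ann = validate_annotation(ann, counts)
    if isinstance(keys, str):
        keys = [keys]
    idx = pd.MultiIndex.from_arrays([ann[k] for k in keys], names=keys)
    codes, uniques = pd.factorize(idx)
    nnz = counts.values.copy()
    nnz.data = np.ones_like(nnz.data)
    onehot = sp.csr_matrix((np.ones(len(codes)), (codes, np.arange(len(codes)))),
                           shape=(len(uniques), len(codes)))
    frac = np.asarray((onehot @ nnz).todense()).T / np.bincount(codes)[None, :]
    cols = [u[0] if len(keys) == 1 else u for u in uniques]
    return pd.DataFrame(frac, index=pd.Index(counts.gene_ids, name="gene"), columns=cols)


def expressed_in_either(frac: pd.DataFrame, columns, threshold: float = 0.2) -> list:
    """Genes whose expressed fraction reaches ``threshold`` in any listed column."""
    return list(frac.index[(frac[list(columns)] >= threshold).any(axis=1)])


def aggregate_one_vs_many(pairwise, lfc_threshold: float = 2.0,
                          use_adjusted: bool = True) -> pd.DataFrame:
    """Aggregate one-vs-each comparisons for a group of interest.

    Per gene: arithmetic mean log2FC, Fisher combination of per-comparison
    adjusted (or raw, with ``use_adjusted=False``) p-values, and the number of
    comparisons whose log2FC exceeds ``lfc_threshold``.
    """
    pairwise = list(pairwise)
    if not pairwise:
        raise ValueError("at least one pairwise comparison is required")
    common = pairwise[0].index
    for r in pairwise[1:]:
        common = common.intersection(r.index)
    if any(len(common) < len(r.index) for r in pairwise):
        warnings.warn("gene universes differ across comparisons; intersecting", stacklevel=2)
    col = "p_adj" if use_adjusted else "p"
    lfc = np.column_stack([r.loc[common, "log2FC"] for r in pairwise])
    pvals = np.column_stack([np.clip(r.loc[common, col], TINY, 1.0) for r in pairwise])
    combined = np.array([fisher_combine(row) for row in pvals])
    return pd.DataFrame(
        {"mean_log2fc": lfc.mean(axis=1),
         "combined_p": combined,
         "n_above_threshold": (lfc > lfc_threshold).sum(axis=1)},
        index=common)


def radial_plot_data(dge_by_celltype: dict, conditions) -> pd.DataFrame:
    """Quadrant table for radial expression plots.

    ``dge_by_celltype`` maps cell type -> DGE result of condition[0] over
    condition[1]. Every gene appears in every (cell type, condition) quadrant;
    a gene not upregulated in a quadrant's condition gets log2FC 0 and
    adjusted p 1.
    """
    cond_a, cond_b = conditions
    rows = []
    for ct, res in dge_by_celltype.items():
        for cond, sign in ((cond_a, 1.0), (cond_b, -1.0)):
            lfc = sign * res["log2FC"].to_numpy()
            padj = res["p_adj"].to_numpy().copy()
            clipped = lfc < 0
            lfc = np.where(clipped, 0.0, lfc)
            padj = np.where(clipped, 1.0, padj)
            rows.append(pd.DataFrame({"cell_type": ct, "condition": cond,
                                      "gene": res.index, "log2FC": lfc, "p_adj": padj}))
    return pd.concat(rows, ignore_index=True)


def select_elevated_genes(agg: pd.DataFrame, frac: pd.Series | None = None,
                          min_log2fc: float = 1.0, max_p_adj: float = 0.05,
                          min_frac: float = 0.2) -> list:
    """Genes elevated in the group of interest: mean log2FC >= min, combined
    p <= max, and (if provided) expressed fraction >= min. All bounds inclusive."""
    keep = (agg["mean_log2fc"] >= min_log2fc) & (agg["combined_p"] <= max_p_adj)
    if frac is not None:
        keep &= frac.reindex(agg.index).fillna(0.0) >= min_frac
    return list(agg.index[keep])
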