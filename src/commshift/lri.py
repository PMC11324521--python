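"""Ligand-receptor interaction scoring and differential communication.

The interaction score for a (sender, receiver, ligand->receptor, condition)
record is the *product* of the sender's mean ligand expression (Lmean) and the
receiver's mean receptor expression (Rmean), computed per condition on the
(non-log) normalized matrix. Using the product rather than the average of the
two means penalizes interactions in which either partner is lowly expressed.
Significance comes from cell-type label permutations: labels are randomly
re-assigned (by default within each condition stratum), all scores are
recomputed, and p is the fraction of permuted scores matching or exceeding
the observed one; a z-score of the observed value against the permutation
background is reported alongside, and BH correction is applied jointly over
all records.

The condition-differential score for a (sender, receiver, pair) record is

    lri_diff = ( log2(Lmean_cKO / Lmean_control)
               + log2(Rmean_cKO / Rmean_control) ) / 2,

the mean (not the product) of the two log2 fold changes, which rewards
coordinated up- or down-regulation of ligand and receptor rather than sheer
magnitude. Its permutation test shuffles the condition labels (by default
within each cell-type stratum, preserving per-type group sizes) and computes
a one-tailed p in the observed direction of change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import NormalizedMatrix, validate_annotation
from .stats import bh_adjust

logger = logging.getLogger(__name__)

LRI_COLUMNS = ("sender", "receiver", "ligand", "receptor", "condition",
               "lmean", "rmean", "lri_score")
DIFF_COLUMNS = ("sender", "receiver", "ligand", "receptor", "lri_diff_score")


@dataclass(frozen=True)
class LRDatabase:
    """Directional ligand->receptor pair list."""

    pairs: tuple  # of (ligand, receptor)
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("LR pairs are not unique")

    @property
    def genes(self) -> list:
        seen: dict = {}
        for lig, rec in self.pairs:
            seen.setdefault(lig, None)
            seen.setdefault(rec, None)
        return list(seen)


@dataclass(frozen=True)
class PermutationConfig:
    n_perm: int = 10_000
    seed: int = 0
    stratified: bool = True  # shuffle within the orthogonal label's strata
    pseudocount: bool = False  # (count+1)/(n_perm+1) p estimator
    condition_tail: str = "doubled"  # "doubled" (calibrated) or "one_sided"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.condition_tail not in ("doubled", "one_sided"):
            raise ValueError("condition_tail must be 'doubled' or 'one_sided'")


def load_lr_pairs(table, norm: NormalizedMatrix, min_frac: float = 0.10,
                  provenance: str = "user table") -> LRDatabase:
    """Build the LR database from a two-column (ligand, receptor) table.

    Reversed duplicates collapse to the first-seen orientation; pairs are
    dropped when either gene is absent from the matrix (warning) or expressed
    in fewer than ``min_frac`` of all cells.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    for col in ("ligand", "receptor"):
        if col not in table.columns:
            raise ValueError(f"LR table is missing column {col!r}")
    present = set(norm.gene_ids)
    frac = pd.Series(norm.values.getnnz(axis=0) / norm.n_cells, index=norm.gene_ids)
    kept, seen, dropped_missing, dropped_frac = [], set(), [], []
    for lig, rec in zip(table["ligand"], table["receptor"]):
        pair = (lig, rec)
        if pair in seen or (rec, lig) in seen:
            continue
        if lig not in present or rec not in present:
            dropped_missing.append(pair)
            seen.add(pair)
            continue
        if frac[lig] < min_frac or frac[rec] < min_frac:
            dropped_frac.append(pair)
            seen.add(pair)
            continue
        seen.add(pair)
        kept.append(pair)
    if dropped_missing:
        warnings.warn(f"{len(dropped_missing)} LR pairs dropped (gene not in matrix), "
                      f"e.g. {dropped_missing[:3]}", stacklevel=2)
    if dropped_frac:
        logger.info("%d LR pairs dropped by the %.0f%% expression filter",
                    len(dropped_frac), 100 * min_frac)
    if not kept:
        raise ValueError("no LR pairs survive filtering")
    return LRDatabase(tuple(kept), provenance=provenance)


class GroupMeans:
    """Mean normalized expression per gene per (cell type, condition)."""

    def __init__(self, means: pd.DataFrame, n_cells: pd.Series):
        self.means = means  # genes x MultiIndex (cell_type, condition)
        self.n_cells = n_cells

    @property
    def cell_types(self) -> list:
        return list(dict.fromkeys(ct for ct, _ in self.means.columns))

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(c for _, c in self.means.columns))

    def get(self, gene, cell_type, condition) -> float:
        return float(self.means.at[gene, (cell_type, condition)])


def group_means(norm: NormalizedMatrix, ann: pd.DataFrame,
                celltype_key: str = "cell_type", condition_key: str = "condition") -> GroupMeans:
    """Arithmetic per-(type, condition) means of the normalized matrix."""
    ann = validate_annotation(ann, norm)
    idx = pd.MultiIndex.from_arrays([ann[celltype_key], ann[condition_key]],
                                    names=["cell_type", "condition"])
    codes, uniques = pd.factorize(idx)
    counts = np.bincount(codes)
    onehot = sp.csr_matrix((np.ones(len(codes)), (codes, np.arange(len(codes)))),
                           shape=(len(uniques), len(codes)))
    sums = np.asarray((onehot @ norm.values).todense())
    means = pd.DataFrame(sums.T / counts[None, :],
                         index=pd.Index(norm.gene_ids, name="gene"),
                         columns=pd.MultiIndex.from_tuples(uniques,
                                                           names=["cell_type", "condition"]))
    means = means.sort_index(axis=1)
    n = pd.Series(counts, index=pd.MultiIndex.from_tuples(uniques)).sort_index()
    return GroupMeans(means, n)


def _record_frame(means: GroupMeans, db: LRDatabase):
    """All (sender, receiver, pair, condition) records with means and scores."""
    rows = []
    types = means.cell_types
    conds = means.conditions
    have = set(means.means.columns)
    for lig, rec in db.pairs:
        for s in types:
            for r in types:
                for c in conds:
                    if (s, c) not in have or (r, c) not in have:
                        logger.warning("skipping %s->%s in %s: empty group", s, r, c)
                        continue
                    lm = means.means.at[lig, (s, c)]
                    rm = means.means.at[rec, (r, c)]
                    rows.append((s, r, lig, rec, c, lm, rm, lm * rm))
    return pd.DataFrame(rows, columns=LRI_COLUMNS)


def lri_scores(means: GroupMeans, db: LRDatabase) -> pd.DataFrame:
    """Observed LRI scores (no inference): one row per record."""
    return _record_frame(means, db)


def lri_diff(means: GroupMeans, db: LRDatabase, epsilon: float = 1e-9,
             conditions=None) -> pd.DataFrame:
    """Observed condition-differential scores, cKO-like over control-like.

    ``conditions`` is (control, cKO); defaults to the sorted condition order.
    With ``epsilon=0`` a structurally zero mean yields an undefined (NaN,
    flagged) score instead of +-inf.
    """
    conds = list(conditions) if conditions is not None else means.conditions
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    ctrl, cko = conds
    scores = _record_frame(means, db)
    wide = scores.pivot_table(index=["sender", "receiver", "ligand", "receptor"],
                              columns="condition", values=["lmean", "rmean"], sort=False)
    L0 = wide[("lmean", ctrl)].to_numpy() + epsilon
    L1 = wide[("lmean", cko)].to_numpy() + epsilon
    R0 = wide[("rmean", ctrl)].to_numpy() + epsilon
    R1 = wide[("rmean", cko)].to_numpy() + epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 0.5 * (np.log2(L1 / L0) + np.log2(R1 / R0))
    undefined = ~np.isfinite(d)
    d = np.where(undefined, np.nan, d)
    out = wide.index.to_frame(index=False)
    out["lri_diff_score"] = d
    out["undefined"] = undefined
    return out


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _grid_means(X: np.ndarray, comb: np.ndarray, n_blocks: int) -> np.ndarray:
    """Per-block means over cells; ``comb`` is a flat block code per cell.

    Returns an (n_blocks x G) array with NaN rows for empty blocks.
    """
    order = np.argsort(comb, kind="stable")
    sizes = np.bincount(comb, minlength=n_blocks)
    nonempty = np.flatnonzero(sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)])[nonempty]
    sums = np.add.reduceat(X[order], starts, axis=0)
    means = np.full((n_blocks, X.shape[1]), np.nan)
    means[nonempty] = sums / sizes[nonempty][:, None]
    return means


def _stratum_indices(strata_codes: np.ndarray | None, n: int) -> list:
    if strata_codes is None:
        return [np.arange(n)]
    return [np.flatnonzero(strata_codes == s) for s in np.unique(strata_codes)]


def _permute_within(labels: np.ndarray, strata: list, rng: np.random.Generator) -> np.ndarray:
    """Shuffle the label vector within each stratum (one stratum = global shuffle)."""
    out = labels.copy()
    for idx in strata:
        out[idx] = labels[idx][rng.permutation(len(idx))]
    return out


def _prepare(norm: NormalizedMatrix, ann: pd.DataFrame, db: LRDatabase,
             celltype_key: str, condition_key: str):
    ann = validate_annotation(ann, norm)
    genes = db.genes
    X = norm.dense(genes=genes)
    gcol = {g: j for j, g in enumerate(genes)}
    type_codes, type_names = pd.factorize(ann[celltype_key], sort=True)
    cond_codes, cond_names = pd.factorize(ann[condition_key], sort=True)
    if len(type_names) < 2:
        raise ValueError("need at least two cell types for a label permutation test")
    return ann, X, gcol, type_codes, list(type_names), cond_codes, list(cond_names)


def permutation_test_celltype(norm: NormalizedMatrix, ann: pd.DataFrame, db: LRDatabase,
                              config: PermutationConfig = PermutationConfig(),
                              celltype_key: str = "cell_type",
                              condition_key: str = "condition") -> pd.DataFrame:
    """LRI scores with cell-type-label permutation p, joint BH p_adj and z.

    With ``config.stratified`` (default) type labels are shuffled within each
    condition, keeping the per-condition type composition fixed; otherwise the
    label vector is shuffled globally across all cells. The same permutation
    sequence is shared by every record.
    """
    (ann, X, gcol, type_codes, type_names,
     cond_codes, cond_names) = _prepare(norm, ann, db, celltype_key, condition_key)
    n_types, n_conds = len(type_names), len(cond_names)
    n_blocks = n_types * n_conds

    def _block(t: int, c: int) -> int:
        return c * n_types + t

    obs_means = _grid_means(X, cond_codes * n_types + type_codes, n_blocks)
    present = ~np.isnan(obs_means[:, 0])
    strata = _stratum_indices(cond_codes if config.stratified else None, len(type_codes))

    rows = []
    for lig, rec in db.pairs:
        for si, s in enumerate(type_names):
            for ri, r in enumerate(type_names):
                for ci, c in enumerate(cond_names):
                    if not (present[_block(si, ci)] and present[_block(ri, ci)]):
                        logger.warning("skipping %s->%s in %s: empty group", s, r, c)
                        continue
                    rows.append((s, r, lig, rec, c,
                                 _block(si, ci), gcol[lig], _block(ri, ci), gcol[rec]))
    rec_df = pd.DataFrame(rows, columns=["sender", "receiver", "ligand", "receptor",
                                         "condition", "_bL", "_gL", "_bR", "_gR"])
    bL = rec_df["_bL"].to_numpy()
    gL = rec_df["_gL"].to_numpy()
    bR = rec_df["_bR"].to_numpy()
    gR = rec_df["_gR"].to_numpy()
    lmean = obs_means[bL, gL]
    rmean = obs_means[bR, gR]
    obs = lmean * rmean

    rng = np.random.default_rng(config.seed)
    count_ge = np.zeros(len(rec_df), dtype=np.int64)
    ssum = np.zeros(len(rec_df))
    ssq = np.zeros(len(rec_df))
    n_eff = np.zeros(len(rec_df), dtype=np.int64)
    for _ in range(config.n_perm):
        ptype = _permute_within(type_codes, strata, rng)
        pm = _grid_means(X, cond_codes * n_types + ptype, n_blocks)
        score = pm[bL, gL] * pm[bR, gR]
        ok = np.isfinite(score)  # a permuted group may be empty in global mode
        count_ge += ok & (score >= obs)
        ssum += np.where(ok, score, 0.0)
        ssq += np.where(ok, score * score, 0.0)
        n_eff += ok
    if config.pseudocount:
        p = (count_ge + 1) / (config.n_perm + 1)
    else:
        p = count_ge / config.n_perm
    denom = np.maximum(n_eff, 1)
    pmean = ssum / denom
    pvar = np.maximum(ssq / denom - pmean ** 2, 0.0)
    psd = np.sqrt(pvar)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(psd > 0, (obs - pmean) / psd, 0.0)

    out = rec_df.drop(columns=["_bL", "_gL", "_bR", "_gR"]).copy()
    out["lmean"] = lmean
    out["rmean"] = rmean
    out["lri_score"] = obs
    out["p"] = p
    out["p_adj"] = bh_adjust(p)
    out["z"] = z
    return out


def permutation_test_condition(norm: NormalizedMatrix, ann: pd.DataFrame, db: LRDatabase,
                               config: PermutationConfig = PermutationConfig(),
                               epsilon: float = 1e-9,
                               conditions=None,
                               celltype_key: str = "cell_type",
                               condition_key: str = "condition") -> pd.DataFrame:
    """Differential scores with direction-sensitive condition-permutation p.

    Condition labels are shuffled (within each cell type when
    ``config.stratified``), the differential score is recomputed per
    permutation, and the tail is taken in the observed direction: for obs >= 0
    the fraction of permuted scores >= obs, for obs < 0 the fraction <= obs.
    Because the tail is chosen after seeing the sign, the raw tail fraction is
    half-sized under a symmetric null; the default ``condition_tail="doubled"``
    doubles it (capped at 1) so the reported p is calibrated, with the
    direction of change carried by the score's sign.
    ``condition_tail="one_sided"`` reports the raw tail fraction instead.
    BH runs jointly over all records.
    """
    (ann, X, gcol, type_codes, type_names,
     cond_codes, cond_names) = _prepare(norm, ann, db, celltype_key, condition_key)
    if len(cond_names) != 2:
        raise ValueError(f"need exactly two conditions, got {cond_names}")
    conds = list(conditions) if conditions is not None else cond_names
    ctrl, cko = conds
    i_ctrl, i_cko = cond_names.index(ctrl), cond_names.index(cko)
    n_types, n_conds = len(type_names), 2
    n_blocks = n_types * n_conds

    def _block(t: int, c: int) -> int:
        return t * n_conds + c

    obs_grid = _grid_means(X, type_codes * n_conds + cond_codes, n_blocks)
    present = ~np.isnan(obs_grid[:, 0])
    strata = _stratum_indices(type_codes if config.stratified else None, len(type_codes))

    rows = []
    for lig, rec in db.pairs:
        for si, s in enumerate(type_names):
            for ri, r in enumerate(type_names):
                needed = [_block(si, i_ctrl), _block(si, i_cko),
                          _block(ri, i_ctrl), _block(ri, i_cko)]
                if not all(present[b] for b in needed):
                    logger.warning("skipping %s->%s: a (type, condition) group is empty", s, r)
                    continue
                rows.append((s, r, lig, rec,
                             needed[0], needed[1], gcol[lig],
                             needed[2], needed[3], gcol[rec]))
    rec_df = pd.DataFrame(rows, columns=["sender", "receiver", "ligand", "receptor",
                                         "_bL0", "_bL1", "_gL", "_bR0", "_bR1", "_gR"])
    bL0 = rec_df["_bL0"].to_numpy()
    bL1 = rec_df["_bL1"].to_numpy()
    gL = rec_df["_gL"].to_numpy()
    bR0 = rec_df["_bR0"].to_numpy()
    bR1 = rec_df["_bR1"].to_numpy()
    gR = rec_df["_gR"].to_numpy()

    def _diff(means: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return 0.5 * (np.log2((means[bL1, gL] + epsilon) / (means[bL0, gL] + epsilon))
                          + np.log2((means[bR1, gR] + epsilon) / (means[bR0, gR] + epsilon)))

    obs = _diff(obs_grid)
    finite = np.isfinite(obs)

    rng = np.random.default_rng(config.seed)
    count_dir = np.zeros(len(rec_df), dtype=np.int64)
    pos = obs >= 0
    for _ in range(config.n_perm):
        pcond = _permute_within(cond_codes, strata, rng)
        d = _diff(_grid_means(X, type_codes * n_conds + pcond, n_blocks))
        ok = np.isfinite(d)
        count_dir += ok & np.where(pos, d >= obs, d <= obs)
    if config.pseudocount:
        p = (count_dir + 1) / (config.n_perm + 1)
    else:
        p = count_dir / config.n_perm
    if config.condition_tail == "doubled":
        p = np.minimum(2.0 * p, 1.0)
    p = np.where(finite, p, np.nan)

    out = rec_df.drop(columns=["_bL0", "_bL1", "_gL", "_bR0", "_bR1", "_gR"]).copy()
    out["lri_diff_score"] = np.where(finite, obs, np.nan)
    out["undefined"] = ~finite
    out["p"] = p
    padj = np.full(len(p), np.nan)
    padj[finite] = bh_adjust(p[finite])
    out["p_adj"] = padj
    return out


def significant_interactions(lri: pd.DataFrame, diff: pd.DataFrame,
                             max_p_adj: float = 0.05, min_abs_diff: float = 1.0,
                             directional: bool = False) -> pd.DataFrame:
    """Published significance filter on differential records.

    Keep (sender, receiver, pair) records whose LRI score is significant
    (p_adj <= max) in at least one condition, whose differential p_adj is
    <= max, and whose |diff score| >= min (score >= min if ``directional``).
    """
    key = ["sender", "receiver", "ligand", "receptor"]
    lri_ok = (lri[lri["p_adj"] <= max_p_adj].groupby(key).size())
    d = diff.set_index(key)
    keep = d.index.isin(lri_ok.index) & (d["p_adj"] <= max_p_adj)
    mag = d["lri_diff_score"] if directional else d["lri_diff_score"].abs()
    keep &= (mag >= min_abs_diff).to_numpy()
    return d[keep].reset_index()


def count_significant_by_pair(filtered: pd.DataFrame) -> pd.DataFrame:
    """Sender x receiver table of significant-interaction counts."""
    if filtered.empty:
        return pd.DataFrame()
    return (filtered.groupby(["sender", "receiver"]).size()
            .unstack(fill_value=0))


def minmax_scale_pairs(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise min-max scaling across condition columns into [0, 1].

    Rows with a constant value map to 0 by convention (logged).
    """
    x = values.to_numpy(dtype=float)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    constant = (span == 0).ravel()
    if constant.any():
        logger.info("%d constant rows min-max scaled to 0", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return pd.DataFrame(scaled, index=values.index, columns=values.columns)
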