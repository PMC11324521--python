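"""End-to-end orchestration: standard-format I/O, configuration, run manifest.

A run goes qc -> normalize -> (dge | lri | lri_diff | modules) as toggled.
All stage randomness derives deterministically from one global seed, so two
runs with the same config and inputs write byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from . import dge as dge_mod
from . import lri as lri_mod
from . import qc as qc_mod
from . import trajectory as traj_mod
from .containers import CountMatrix, NormalizedMatrix, validate_annotation

logger = logging.getLogger(__name__)

STAGES = ("qc", "dge", "lri", "lri_diff", "modules")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def read_counts(directory) -> CountMatrix:
    """Read a matrix.mtx / barcodes.tsv / features.tsv triplet (optionally .gz).

    The matrix is stored genes x cells (rows = features) and transposed on
    read; duplicate coordinate entries are summed.
    """
    directory = Path(directory)

    def _find(stem: str) -> Path:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
        raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")

    mtx_path = _find("matrix.mtx")
    bc_path = _find("barcodes.tsv")
    ft_path = _find("features.tsv")
    try:
        mat = mmread(mtx_path)
    except Exception as exc:
        raise ValueError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat).T.tocsr()  # duplicate entries are summed by CSR conversion
    mat.sum_duplicates()
    barcodes = pd.read_csv(bc_path, header=None, sep="\t")[0].to_numpy(dtype=object)
    features = pd.read_csv(ft_path, header=None, sep="\t")[0].to_numpy(dtype=object)
    if mat.shape[0] != len(barcodes):
        raise ValueError(f"{mtx_path}: {mat.shape[0]} cells but "
                         f"{len(barcodes)} barcodes in {bc_path}")
    if mat.shape[1] != len(features):
        raise ValueError(f"{mtx_path}: {mat.shape[1]} genes but "
                         f"{len(features)} features in {ft_path}")
    return CountMatrix(mat, barcodes, features)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, index_col="cell_id")
    return ann


@dataclass
class PipelineConfig:
    counts_dir: str
    cells_path: str
    out_dir: str
    lr_path: str | None = None
    # stage toggles
    run_dge: bool = True
    run_lri: bool = True
    run_lri_diff: bool = True
    run_modules: bool = True
    # qc / normalization
    mito_prefix: str = "mt-"
    hemo_prefix: str = "Hb"
    thresholds: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    n_hvg: int = 4000
    # dge
    celltype_key: str = "cell_type"
    condition_key: str = "condition"
    sample_key: str = "sample"
    min_frac_expressed: float = 0.2
    # lri
    n_perm: int = 10_000
    min_frac_lr: float = 0.10
    conditions: tuple | None = None  # (control, treatment); sorted order if None
    epsilon: float = 1e-9
    max_p_adj: float = 0.05
    min_abs_diff: float = 1.0
    # modules
    n_bins: int = 21
    r_min: float = 0.5
    resolution: float = 1.0
    n_hvg_modules: int = 8000
    seed: int = 0

    def validate(self) -> None:
        for name in ("counts_dir", "cells_path"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} does not exist: {getattr(self, name)}")
        if (self.run_lri or self.run_lri_diff) and (
                self.lr_path is None or not Path(self.lr_path).exists()):
            raise FileNotFoundError("lr_path is required for the lri stages")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the toggled stages; returns the run manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                       for k, v in dataclasses.asdict(config).items()},
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }
    for p in sorted(Path(config.counts_dir).glob("*")):
        if p.is_file():
            manifest["inputs"][p.name] = _sha256(p)
    manifest["inputs"][Path(config.cells_path).name] = _sha256(config.cells_path)
    if config.lr_path:
        manifest["inputs"][Path(config.lr_path).name] = _sha256(config.lr_path)

    def _stage(name):
        t0 = time.perf_counter()
        manifest["stages"][name] = {"seed": stage_seed(config.seed, name)}

        def _done(**counts):
            manifest["stages"][name].update(counts)
            manifest["stages"][name]["seconds"] = round(time.perf_counter() - t0, 3)
        return _done

    # --- qc + normalize (always run) ---
    done = _stage("qc")
    counts = read_counts(config.counts_dir)
    ann = read_annotation(config.cells_path)
    mito = qc_mod.genes_by_prefix(counts.gene_ids, config.mito_prefix)
    hemo = qc_mod.genes_by_prefix(counts.gene_ids, config.hemo_prefix)
    metrics = qc_mod.barcode_metrics(counts, mito, hemo)
    metrics.to_csv(out / "metrics.csv")
    kept_cells = qc_mod.filter_barcodes(metrics, config.thresholds)
    kept_genes = qc_mod.filter_genes(counts, config.thresholds)
    (out / "kept_cells.txt").write_text("".join(f"{c}\n" for c in kept_cells))
    (out / "kept_genes.txt").write_text("".join(f"{g}\n" for g in kept_genes))
    counts = counts.subset(cells=kept_cells, genes=kept_genes)
    ann = validate_annotation(ann, counts)
    norm = qc_mod.normalize(counts)
    mmwrite(out / "normalized.mtx", norm.values.T.tocoo())
    hvg = qc_mod.select_hvg(norm, min(config.n_hvg, norm.n_genes))
    (out / "hvg.txt").write_text("".join(f"{g}\n" for g in hvg))
    done(n_cells=len(kept_cells), n_genes=len(kept_genes), n_hvg=len(hvg))

    # --- dge ---
    if config.run_dge:
        done = _stage("dge")
        conds = sorted(ann[config.condition_key].unique())
        frac = dge_mod.frac_expressed(counts, ann,
                                      keys=[config.celltype_key, config.condition_key])
        per_ct = {}
        for ct in sorted(ann[config.celltype_key].unique()):
            sub_cells = ann.index[ann[config.celltype_key] == ct]
            sub = counts.subset(cells=list(sub_cells))
            sub_ann = ann.loc[sub_cells]
            if sub_ann[config.condition_key].nunique() < 2:
                logger.warning("skipping DGE for %s: fewer than two conditions", ct)
                continue
            pb_ct = dge_mod.make_pseudobulk(sub, sub_ann, group_key=config.condition_key,
                                            sample_key=config.sample_key)
            cols = [(ct, c) for c in conds if (ct, c) in frac.columns]
            genes = dge_mod.expressed_in_either(frac, cols, config.min_frac_expressed)
            genes = [g for g in genes if g in pb_ct.columns]
            res = dge_mod.nb_wald_test(pb_ct[genes], conds[0], conds[1])
            res.to_csv(out / f"dge_{ct}_{conds[0]}_vs_{conds[1]}.csv")
            per_ct[ct] = res
        radial = dge_mod.radial_plot_data(per_ct, conds)
        radial.to_csv(out / "radial.csv", index=False)
        done(n_celltypes=len(per_ct), n_radial_rows=len(radial))

    # --- lri / lri_diff ---
    db = None
    lri_res = diff_res = None
    if config.run_lri or config.run_lri_diff:
        db = lri_mod.load_lr_pairs(config.lr_path, norm, min_frac=config.min_frac_lr)
    if config.run_lri:
        done = _stage("lri")
        pc = lri_mod.PermutationConfig(n_perm=config.n_perm,
                                       seed=stage_seed(config.seed, "lri"))
        lri_res = lri_mod.permutation_test_celltype(
            norm, ann, db, pc, celltype_key=config.celltype_key,
            condition_key=config.condition_key)
        lri_res.to_csv(out / "lri_scores.csv", index=False)
        done(n_records=len(lri_res))
    if config.run_lri_diff:
        done = _stage("lri_diff")
        pc = lri_mod.PermutationConfig(n_perm=config.n_perm,
                                       seed=stage_seed(config.seed, "lri_diff"))
        diff_res = lri_mod.permutation_test_condition(
            norm, ann, db, pc, epsilon=config.epsilon, conditions=config.conditions,
            celltype_key=config.celltype_key, condition_key=config.condition_key)
        diff_res.to_csv(out / "lri_diff.csv", index=False)
        if lri_res is not None:
            signif = lri_mod.significant_interactions(
                lri_res, diff_res, max_p_adj=config.max_p_adj,
                min_abs_diff=config.min_abs_diff)
            signif.to_csv(out / "lri_significant.csv", index=False)
            counts_tbl = lri_mod.count_significant_by_pair(signif)
            counts_tbl.to_csv(out / "lri_counts.csv")
            done(n_records=len(diff_res), n_significant=len(signif))
        else:
            done(n_records=len(diff_res))

    # --- modules ---
    if config.run_modules:
        done = _stage("modules")
        if "pseudotime" not in ann.columns or ann["pseudotime"].dropna().empty:
            logger.warning("no pseudotime in annotation; skipping module stage")
            manifest["stages"]["modules"]["skipped"] = "no pseudotime"
        else:
            bins = traj_mod.bin_pseudotime(ann["pseudotime"], n_bins=config.n_bins)
            bins.to_frame().to_csv(out / "bins.csv")
            lineage_cells = list(bins.index)
            sub = counts.subset(cells=lineage_cells)
            sub_norm = qc_mod.normalize(sub)
            n_hvg = min(config.n_hvg_modules, sub_norm.n_genes)
            hvg = qc_mod.select_hvg(sub_norm, n_hvg)
            profiles = traj_mod.bin_profiles(sub_norm, bins, hvg)
            edges = traj_mod.correlation_graph(profiles, r_min=config.r_min)
            assignment = traj_mod.leiden_modules(
                edges, profiles.index, resolution=config.resolution,
                seed=stage_seed(config.seed, "modules"))
            assignment.to_frame().to_csv(out / "modules.csv")
            summaries = traj_mod.module_summaries(assignment, profiles)
            summaries.to_csv(out / "module_profiles.csv", index=False)
            clustered = assignment[assignment != traj_mod.UNCLUSTERED]
            done(n_lineage_cells=len(lineage_cells), n_edges=len(edges),
                 n_modules=int(clustered.nunique()))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
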