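"""Synthetic scRNA-seq generator with planted ligand-receptor effects.

Counts are drawn from a negative binomial (gamma-Poisson) model,
``K ~ NB(mean = s_c * mu[g, type(c), cond(c), t(c)], size = theta)`` with
``Var = mu + mu^2 / theta``. Per-cell-type gene means are log-normal, so cell
types carry genuine marker structure; per-cell size factors are log-normal
with unit mean. Planted ligand-receptor interactions multiply the ligand mean
in the sender type and the receptor mean in the receiver type by
condition-specific fold factors; an optional pseudotime lineage gives selected
gene sets smooth temporal profiles (sigmoid up/down, transient bump, flat).

Every dataset comes with a :class:`SimulationTruth` carrying the planted
effects, so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .containers import CountMatrix

PROFILE_SHAPES = ("sigmoid_up", "sigmoid_down", "bump", "flat")


@dataclass(frozen=True)
class PlantedInteraction:
    """One planted ligand-receptor effect.

    Fold factors are keyed by condition name; a missing condition means fold 1.
    """

    ligand: str
    receptor: str
    sender: str
    receiver: str
    ligand_fold: dict = field(default_factory=dict)
    receptor_fold: dict = field(default_factory=dict)

    def fold(self, role: str, condition: str) -> float:
        table = self.ligand_fold if role == "ligand" else self.receptor_fold
        return float(table.get(condition, 1.0))


@dataclass(frozen=True)
class ModuleSpec:
    """A gene set following one temporal profile along the lineage."""

    name: str
    genes: tuple
    shape: str  # one of PROFILE_SHAPES
    amplitude: float = 8.0  # fold range low -> high of the profile


@dataclass(frozen=True)
class TrajectorySpec:
    lineage_cell_types: tuple
    modules: tuple = ()
    steepness: float = 10.0  # logistic slope for sigmoid shapes
    bump_sigma: float = 0.15


@dataclass
class SimulationConfig:
    n_cell_types: int = 4
    cells_per_type_per_condition: int = 200
    n_genes: int = 300
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    libsize_sigma: float = 0.3
    conditions: tuple = ("control", "cKO")
    cell_types: tuple | None = None
    n_samples_per_condition: int = 3
    gene_lognorm_sigma: float = 1.0
    type_lognorm_sigma: float = 0.8
    planted_interactions: tuple = ()
    n_background_pairs: int = 10
    lr_gene_mean: float = 2.0
    marker_elevation: float = 2.0
    trajectory: TrajectorySpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "cells_per_type_per_condition", "n_genes",
                     "n_samples_per_condition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimulationConfig.{name} must be positive")
        for name in ("baseline_mean", "dispersion", "lr_gene_mean", "marker_elevation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimulationConfig.{name} must be positive")
        if self.libsize_sigma < 0:
            raise ValueError("SimulationConfig.libsize_sigma must be nonnegative")
        if len(self.conditions) != 2:
            raise ValueError("SimulationConfig.conditions must name exactly two conditions")
        if self.cell_types is None:
            self.cell_types = tuple(f"type{i}" for i in range(self.n_cell_types))
        self.cell_types = tuple(self.cell_types)
        self.n_cell_types = len(self.cell_types)
        self.planted_interactions = tuple(self.planted_interactions)
        seen = set()
        for pi in self.planted_interactions:
            for role in ("ligand", "receptor"):
                for cond in self.conditions:
                    if pi.fold(role, cond) <= 0:
                        raise ValueError(
                            f"planted_interactions: fold for {getattr(pi, role)} must be > 0")
            if pi.ligand == pi.receptor:
                raise ValueError("planted_interactions: ligand and receptor genes must differ")
            if (pi.ligand, pi.receptor) in seen:
                raise ValueError(f"duplicate planted pair {(pi.ligand, pi.receptor)}")
            seen.add((pi.ligand, pi.receptor))
            for t in (pi.sender, pi.receiver):
                if t not in self.cell_types:
                    raise ValueError(f"planted_interactions: unknown cell type {t!r}")
        if self.trajectory is not None:
            all_genes: set = set()
            for mod in self.trajectory.modules:
                if mod.shape not in PROFILE_SHAPES:
                    raise ValueError(f"trajectory: unknown profile shape {mod.shape!r}")
                overlap = all_genes & set(mod.genes)
                if overlap:
                    raise ValueError(f"trajectory: module gene sets overlap: {sorted(overlap)[:3]}")
                all_genes |= set(mod.genes)
            for t in self.trajectory.lineage_cell_types:
                if t not in self.cell_types:
                    raise ValueError(f"trajectory: unknown lineage cell type {t!r}")


@dataclass
class SimulationTruth:
    """Planted ground truth: LRI diff scores, module membership, pseudotime."""

    true_lri_diff: pd.DataFrame  # sender, receiver, ligand, receptor, true_lri_diff
    module_membership: dict  # gene -> module name (planted genes only)
    true_pseudotime: pd.Series  # per lineage cell
    lr_pairs: pd.DataFrame  # ligand, receptor, planted (bool)

    def to_json(self) -> str:
        payload = {
            "true_lri_diff": self.true_lri_diff.to_dict(orient="records"),
            "module_membership": dict(self.module_membership),
            "true_pseudotime": {k: float(v) for k, v in self.true_pseudotime.items()},
            "lr_pairs": self.lr_pairs.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _profile(shape: str, t: np.ndarray, spec: TrajectorySpec, amplitude: float) -> np.ndarray:
    """Mean multiplier m(t) in [1, amplitude]."""
    if shape == "flat":
        return np.ones_like(t)
    if shape == "sigmoid_up":
        u = 1.0 / (1.0 + np.exp(-spec.steepness * (t - 0.5)))
    elif shape == "sigmoid_down":
        u = 1.0 / (1.0 + np.exp(spec.steepness * (t - 0.5)))
    elif shape == "bump":
        u = np.exp(-0.5 * ((t - 0.5) / spec.bump_sigma) ** 2)
    else:  # pragma: no cover - guarded in config validation
        raise ValueError(shape)
    return 1.0 + (amplitude - 1.0) * u


def _gene_names(n: int) -> np.ndarray:
    return np.array([f"g{i:05d}" for i in range(n)], dtype=object)


def simulate_dataset(config: SimulationConfig):
    """Draw one dataset; returns ``(CountMatrix, annotation, SimulationTruth)``.

    Deterministic for a fixed config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_types = config.n_cell_types
    conds = config.conditions
    n_per = config.cells_per_type_per_condition
    n_cells = n_types * len(conds) * n_per

    # base gene means: gene-level log-normal around baseline_mean, then a
    # per-(gene, type) log-normal factor for marker structure
    gene_base = config.baseline_mean * rng.lognormal(
        -0.5 * config.gene_lognorm_sigma ** 2, config.gene_lognorm_sigma, config.n_genes)
    type_factor = rng.lognormal(
        -0.5 * config.type_lognorm_sigma ** 2, config.type_lognorm_sigma,
        (n_types, config.n_genes))

    # LR genes (planted + background) get a fixed, well-expressed baseline so
    # the 10%-expression filter is meaningful rather than a lottery
    planted_genes = set()
    for pi in config.planted_interactions:
        planted_genes |= {pi.ligand, pi.receptor}
    bg_pairs = []
    if config.n_background_pairs:
        candidates = [g for g in genes if g not in planted_genes]
        if len(candidates) < 2 * config.n_background_pairs:
            raise ValueError("not enough free genes for the requested background LR pairs")
        picked = rng.choice(len(candidates), size=2 * config.n_background_pairs, replace=False)
        for k in range(config.n_background_pairs):
            bg_pairs.append((candidates[picked[2 * k]], candidates[picked[2 * k + 1]]))
    lr_genes = planted_genes | {g for p in bg_pairs for g in p}
    for g in lr_genes:
        j = gene_pos[g]
        gene_base[j] = config.lr_gene_mean
        type_factor[:, j] = 1.0

    # mu[type, cond, gene]
    mu = np.empty((n_types, len(conds), config.n_genes))
    for ti in range(n_types):
        mu[ti, :, :] = gene_base * type_factor[ti]
    type_idx = {t: i for i, t in enumerate(config.cell_types)}
    for pi in config.planted_interactions:
        si, ri = type_idx[pi.sender], type_idx[pi.receiver]
        lj, rj = gene_pos[pi.ligand], gene_pos[pi.receptor]
        mu[si, :, lj] *= config.marker_elevation
        mu[ri, :, rj] *= config.marker_elevation
        for ci, cond in enumerate(conds):
            mu[si, ci, lj] *= pi.fold("ligand", cond)
            mu[ri, ci, rj] *= pi.fold("receptor", cond)

    # cell sheet
    cell_type = np.repeat(np.repeat(list(config.cell_types), len(conds)), n_per)
    condition = np.tile(np.repeat(list(conds), n_per), n_types)
    cell_ids = np.array([f"cell{i:06d}" for i in range(n_cells)], dtype=object)
    sample_no = rng.integers(config.n_samples_per_condition, size=n_cells)
    sample = np.array([f"{c}_s{k}" for c, k in zip(condition, sample_no)], dtype=object)

    # per-cell mean matrix
    ti = np.array([type_idx[t] for t in cell_type])
    ci = np.array([list(conds).index(c) for c in condition])
    M = mu[ti, ci, :]  # cells x genes

    # pseudotime lineage
    pseudotime = np.full(n_cells, np.nan)
    module_membership: dict = {}
    if config.trajectory is not None:
        spec = config.trajectory
        lineage_mask = np.isin(cell_type, list(spec.lineage_cell_types))
        t = rng.uniform(0.0, 1.0, int(lineage_mask.sum()))
        pseudotime[lineage_mask] = t
        M = M.copy()
        for mod in spec.modules:
            cols = [gene_pos[g] for g in mod.genes]
            prof = _profile(mod.shape, t, spec, mod.amplitude)
            M[np.ix_(np.flatnonzero(lineage_mask), cols)] *= prof[:, None]
            for g in mod.genes:
                module_membership[g] = mod.name

    # size factors, unit mean
    if config.libsize_sigma > 0:
        s = rng.lognormal(0.0, config.libsize_sigma, n_cells)
        s /= s.mean()
    else:
        s = np.ones(n_cells)

    theta = config.dispersion
    lam = rng.gamma(shape=theta, scale=(s[:, None] * M) / theta)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(sp.csr_matrix(counts), cell_ids, genes)
    ann = pd.DataFrame(
        {"cell_type": cell_type, "condition": condition, "sample": sample,
         "pseudotime": pseudotime},
        index=pd.Index(cell_ids, name="cell_id"))

    diff_rows = []
    ctrl, cko = conds
    for pi in config.planted_interactions:
        d = 0.5 * (np.log2(pi.fold("ligand", cko) / pi.fold("ligand", ctrl))
                   + np.log2(pi.fold("receptor", cko) / pi.fold("receptor", ctrl)))
        diff_rows.append({"sender": pi.sender, "receiver": pi.receiver,
                          "ligand": pi.ligand, "receptor": pi.receptor,
                          "true_lri_diff": d})
    true_diff = pd.DataFrame(diff_rows,
                             columns=["sender", "receiver", "ligand", "receptor",
                                      "true_lri_diff"])
    pairs = ([{"ligand": pi.ligand, "receptor": pi.receptor, "planted": True}
              for pi in config.planted_interactions]
             + [{"ligand": a, "receptor": b, "planted": False} for a, b in bg_pairs])
    lr_pairs = pd.DataFrame(pairs, columns=["ligand", "receptor", "planted"])
    truth = SimulationTruth(
        true_lri_diff=true_diff,
        module_membership=module_membership,
        true_pseudotime=pd.Series(pseudotime[~np.isnan(pseudotime)],
                                  index=cell_ids[~np.isnan(pseudotime)]),
        lr_pairs=lr_pairs,
    )
    return cm, ann, truth


def qc_violation_fixture():
    """Constructed count matrix in which each QC rule has exactly one violator.

    Twelve clean barcodes cover 1,100 background genes at one count each; five
    additional barcodes each break exactly one barcode rule (UMIs, features,
    mitochondrial %, hemoglobin %, complexity) at the rule's boundary, and
    special genes break the gene rules (note a gene under 10 total counts can
    never reach 10 distinct barcodes, so the low-total violator necessarily
    breaks both gene rules). Returns ``(CountMatrix, expected_kept_barcodes,
    expected_kept_genes)`` under the default thresholds.
    """
    n_bg = 1100
    bg = [f"bg{i:04d}" for i in range(n_bg)]
    genes = bg + ["mt-1", "Hb-1", "lowtotal", "fewbar"]
    gpos = {g: j for j, g in enumerate(genes)}
    barcodes, rows = [], []

    def add(name, counts_by_gene):
        barcodes.append(name)
        row = np.zeros(len(genes), dtype=np.int64)
        for g, c in counts_by_gene.items():
            row[gpos[g]] = c
        rows.append(row)

    for i in range(12):
        extra = {}
        if i < 9:
            extra["lowtotal"] = 1  # 9 counts in 9 barcodes: fails both gene rules
        if i < 5:
            extra["fewbar"] = 3  # 15 counts in 5 barcodes: fails only the barcode rule
        add(f"good{i:02d}", {**{g: 1 for g in bg}, **extra})
    # UMIs: 999 total (< 1000), 999 features
    add("v_umis", {g: 1 for g in bg[:999]})
    # features: 799 features (< 800), total 1100
    add("v_features", {**{g: 1 for g in bg[1:799]}, bg[0]: 302})
    # mito: exactly 15% mitochondrial counts (strict < 15 fails)
    add("v_mito", {**{g: 1 for g in bg[:850]}, "mt-1": 150})
    # hemoglobin: exactly 5%
    add("v_hemo", {**{g: 1 for g in bg[:950]}, "Hb-1": 50})
    # complexity: 800 features over 4257 counts -> log10(800)/log10(4257) < 0.8
    add("v_complexity", {**{g: 1 for g in bg[1:800]}, bg[0]: 3458})

    cm = CountMatrix(sp.csr_matrix(np.vstack(rows)),
                     np.array(barcodes, dtype=object), np.array(genes, dtype=object))
    kept_barcodes = [b for b in barcodes if b.startswith("good")]
    return cm, kept_barcodes, bg


def write_fixture(counts: CountMatrix, ann: pd.DataFrame, truth: SimulationTruth,
                  directory) -> dict:
    """Write a 10x-style on-disk fixture; returns the path of every file written.

    Layout: ``matrix.mtx`` (genes x cells, coordinate integer), ``barcodes.tsv``,
    ``features.tsv``, ``cells.csv``, ``lr_pairs.csv``, ``truth.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / name for name in
             ("matrix.mtx", "barcodes.tsv", "features.tsv", "cells.csv",
              "lr_pairs.csv", "truth.json")}
    mmwrite(paths["matrix.mtx"], counts.values.T.tocoo(), field="integer")
    paths["barcodes.tsv"].write_text("".join(f"{c}\n" for c in counts.cell_ids))
    paths["features.tsv"].write_text("".join(f"{g}\n" for g in counts.gene_ids))
    out = ann.copy()
    out.index.name = "cell_id"
    out.to_csv(paths["cells.csv"])
    truth.lr_pairs[["ligand", "receptor"]].to_csv(paths["lr_pairs.csv"], index=False)
    paths["truth.json"].write_text(truth.to_json())
    return paths
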