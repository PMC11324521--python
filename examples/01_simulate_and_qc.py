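"""Generate a synthetic scRNA-seq dataset and run barcode/gene QC.

Builds a small two-condition dataset with one planted ligand-receptor effect,
writes it as an on-disk MTX fixture, then computes per-barcode QC metrics
(UMIs, features, mitochondrial/hemoglobin %, complexity) and applies the
default filters.
"""

import tempfile
from pathlib import Path

import commshift as cs

out = Path(tempfile.mkdtemp()) / "fixture"
config = cs.SimulationConfig(
    n_cell_types=3, cells_per_type_per_condition=100, n_genes=400,
    planted_interactions=(
        cs.PlantedInteraction("g00100", "g00101", sender="type0", receiver="type1",
                              ligand_fold={"cKO": 4.0}, receptor_fold={"cKO": 4.0}),),
    seed=1)
counts, ann, truth = cs.simulate_dataset(config)
cs.write_fixture(counts, ann, truth, out)
print(f"dataset: {counts.n_cells} cells x {counts.n_genes} genes -> {out}")

metrics = cs.barcode_metrics(counts)
print(metrics.head(3).round(3))
# complexity = log10(n expressed genes)/log10(total counts); values near 1 mean
# counts are spread over many genes, low values flag degenerate libraries.

# synthetic cells are shallow by design, so relax the depth thresholds
thresholds = cs.QCThresholds(min_umis=100, min_features=80, min_complexity=0.5)
kept_cells = cs.filter_barcodes(metrics, thresholds)
kept_genes = cs.filter_genes(counts, thresholds)
print(f"kept {len(kept_cells)}/{counts.n_cells} barcodes, "
      f"{len(kept_genes)}/{counts.n_genes} genes")

norm = cs.normalize(counts.subset(cells=kept_cells, genes=kept_genes))
print(f"size factors: median {norm.size_factors.mean():.3f} "
      f"(range {norm.size_factors.min():.2f}-{norm.size_factors.max():.2f})")
# a size factor of 2 means the cell was sequenced twice as deep as the median
# cell; normalized expression is raw counts divided by this factor.
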