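"""Score ligand-receptor interactions with the cell-type permutation test.

The interaction score for (sender, receiver, ligand->receptor, condition) is
the product of the sender's mean ligand expression and the receiver's mean
receptor expression. Significance comes from shuffling cell-type labels and
recomputing all scores; BH correction runs jointly over every record.
"""

import commshift as cs

config = cs.SimulationConfig(
    n_cell_types=3, cells_per_type_per_condition=150, n_genes=600,
    planted_interactions=(
        cs.PlantedInteraction("g00100", "g00101", sender="type0", receiver="type1",
                              ligand_fold={"cKO": 4.0}, receptor_fold={"cKO": 4.0}),),
    n_background_pairs=10, seed=2)
counts, ann, truth = cs.simulate_dataset(config)
norm = cs.normalize(counts)

# pairs with either gene expressed in < 10% of cells are excluded
db = cs.load_lr_pairs(truth.lr_pairs, norm, min_frac=0.10)
print(f"LR database: {len(db.pairs)} pairs over {len(db.genes)} genes")

res = cs.permutation_test_celltype(
    norm, ann, db, cs.PermutationConfig(n_perm=1000, seed=7))
top = res.sort_values("z", ascending=False).head(5)
cols = ["sender", "receiver", "ligand", "receptor", "condition",
        "lri_score", "p", "p_adj", "z"]
print(top[cols].round(3).to_string(index=False))
# the planted type0 -> type1 interaction tops the list in cKO: its product
# score sits far above the label-permutation background (large z, p_adj ~ 0),
# while background pairs hover near the null.
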