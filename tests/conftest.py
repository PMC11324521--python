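import numpy as np
import pytest

import commshift as cs


@pytest.fixture(scope="session")
def planted_dataset():
    """Small two-condition dataset with one strong planted interaction."""
    config = cs.SimulationConfig(
        n_cell_types=3, cells_per_type_per_condition=60, n_genes=400,
        planted_interactions=(
            cs.PlantedInteraction("g00100", "g00101", "type0", "type1",
                                  ligand_fold={"cKO": 4.0},
                                  receptor_fold={"cKO": 4.0}),
        ),
        n_background_pairs=5, seed=42)
    counts, ann, truth = cs.simulate_dataset(config)
    return config, counts, ann, truth


@pytest.fixture(scope="session")
def normalized(planted_dataset):
    _, counts, ann, _ = planted_dataset
    return cs.normalize(counts), ann


@pytest.fixture(scope="session")
def qc_fixture():
    return cs.sim.qc_violation_fixture()


def simulate_null(seed: int, n_cell_types: int = 4, cells: int = 125,
                  n_genes: int = 300, n_pairs: int = 50):
    """Dataset with real cell types but no condition effect."""
    config = cs.SimulationConfig(
        n_cell_types=n_cell_types, cells_per_type_per_condition=cells,
        n_genes=n_genes, planted_interactions=(), n_background_pairs=n_pairs,
        seed=seed)
    return cs.simulate_dataset(config)
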