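import numpy as np
import pandas as pd
import pytest

from scmetaboscape import ExpressionMatrix, PathwayCollection, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated dataset with a planted high/low metabolic split."""
    cfg = simulate.SimulationConfig(
        n_genes=400,
        n_cells=300,
        n_cell_types=3,
        n_samples=2,
        n_pathways=8,
        genes_per_pathway=12,
        planted_split_fraction=0.5,
        planted_split_boost=3.0,
        seed=42,
    )
    expr, truth = simulate.simulate_dataset(cfg)
    return cfg, expr, truth


@pytest.fixture
def toy_expr():
    """6 genes x 4 cells, two cell types, hand-checkable."""
    values = np.array(
        [
            [2.0, 4.0, 6.0, 6.0],
            [1.0, 1.0, 1.0, 1.0],
            [0.0, 0.0, 3.0, 3.0],
            [5.0, 5.0, 5.0, 5.0],
            [2.0, 2.0, 8.0, 8.0],
            [1.0, 3.0, 2.0, 2.0],
        ]
    )
    ids = ["c1", "c2", "c3", "c4"]
    anno = pd.DataFrame(
        {"cell_type": ["A", "A", "B", "B"], "sample": ["s1", "s1", "s1", "s1"]},
        index=ids,
    )
    return ExpressionMatrix(
        values, [f"g{i}" for i in range(1, 7)], ids, anno, units="normalized"
    )


@pytest.fixture
def toy_pathways():
    return PathwayCollection(
        {"P": ["g1", "g2"], "Q": ["g1", "g3", "g4"], "R": ["g5", "g6"]},
        {"P": "Amino acid metabolism", "Q": "Lipid metabolism"},
    )
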