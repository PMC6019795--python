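import numpy as np
import pandas as pd
import pytest

import heteropath as hp


def make_expr(values, gene_ids=None, sample_ids=None, tissue_of=None):
    """Small expression matrix builder for hand-computed examples."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    if tissue_of is None:
        half = n_samples // 2
        tissue_of = {
            s: ("t1" if j < half else "t2") for j, s in enumerate(sample_ids)
        }
    return hp.ExpressionMatrix(
        data=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        tissue_of=tissue_of,
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """One mean-zero bidirectional pathway planted in brain, plus decoys."""
    config = hp.FixtureConfig(
        n_genes=2000,
        tissues=("brain", "lung", "heart"),
        replicates=3,
        planted=[hp.PlantedPathway("bidir", 50, 0.5, 0.5, 1.0, "brain")],
        n_decoy_sets=20,
        decoy_set_size=50,
    )
    return hp.generate_fixture(config, seed=11)
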