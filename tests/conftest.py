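import warnings

import numpy as np
import pandas as pd
import pytest

from coldnet.expression import ExpressionMatrix
from coldnet.simulate import GenConfig, generate_expression, generate_prior, generate_truth

warnings.filterwarnings("ignore", message="elastic-net refinement skipped")


def make_expression(values, genotypes, times, replicates=None, genes=None):
    """Build an ExpressionMatrix from a dense array with generated sample keys."""
    values = np.asarray(values, dtype=float)
    if replicates:
        cols = [
            f"{g}:{t}:{r}"
            for g in genotypes
            for t in times
            for r in range(1, replicates + 1)
        ]
    else:
        cols = [f"{g}:{t}" for g in genotypes for t in times]
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols))


@pytest.fixture(scope="session")
def small_truth():
    cfg = GenConfig(
        n_genes=120, n_tfs=8, seed=11, n_conserved=1, n_divergent=2,
        set_size=8, n_path_genes=20,
    )
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    x = generate_expression(small_truth)
    prior = generate_prior(small_truth)
    return small_truth, x, prior
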