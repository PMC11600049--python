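import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sctme.core_io import ExpressionDataset


def make_dataset(counts, gene_ids=None, groups=None, clusters=None, samples=None):
    """Build a valid ExpressionDataset around a dense count array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_ids = gene_ids or [f"G{j}" for j in range(n_genes)]
    cell_ids = [f"cell{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample_id": samples or ["s0"] * n_cells,
            "group": groups or ["MPLC_Tumour"] * n_cells,
            "cluster": clusters or ["c0"] * n_cells,
        },
        index=cell_ids,
    )
    return ExpressionDataset(
        counts=sp.csr_matrix(counts), gene_ids=gene_ids, cell_ids=cell_ids, meta=meta
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def auc_by_pair_counting(in_vals, out_vals):
    """Brute-force AUC: all (in, out) pairs, ties counted half."""
    wins = 0.0
    for a in in_vals:
        for b in out_vals:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(in_vals) * len(out_vals))
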