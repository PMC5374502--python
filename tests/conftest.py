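import numpy as np
import pandas as pd
import pytest

from scmge import preprocess as pp
from scmge import synthetic_data as sd
from scmge.io_model import CountMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic MGE-like cohort (seed 0), shared across tests."""
    cfg = sd.default_config(seed=0)
    counts, truth = sd.simulate_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def qc_kept(default_cohort):
    _, counts, _ = default_cohort
    metrics = pp.compute_qc_metrics(counts)
    return pp.filter_cells(metrics)


@pytest.fixture(scope="session")
def reference(default_cohort):
    cfg, _, _ = default_cohort
    return sd.simulate_reference(cfg)


def make_counts(values, gene_ids=None, cell_ids=None, lengths=None, mito=None,
                total_reads=None, unit="reads"):
    """Hand-build a small CountMatrix for arithmetic examples."""
    values = np.asarray(values)
    n_g, n_c = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_g)]
    cell_ids = cell_ids or [f"c{j}" for j in range(n_c)]
    genes = pd.DataFrame(
        {
            "symbol": gene_ids,
            "length_bp": lengths if lengths is not None else [1000] * n_g,
            "is_mitochondrial": mito if mito is not None else [False] * n_g,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cells = pd.DataFrame(
        {
            "condition": ["E11.5"] * n_c,
            "total_mapped_reads": total_reads if total_reads is not None else [3_000_000] * n_c,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CountMatrix(pd.DataFrame(values, index=genes.index, columns=cells.index),
                       genes, cells, unit=unit)
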