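import numpy as np
import pandas as pd
import pytest

import stressomics as so


@pytest.fixture(scope="session")
def small_sim():
    """A small but full multi-omics simulation shared across tests."""
    cfg = so.SimConfig(n_genes=300, seed=7)
    return cfg, so.generate_multiomics(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    cfg, data = small_sim
    res = so.run_event_pipeline(data.counts, peptide_counts=data.peptides)
    return cfg, data, res


def make_count_matrix(values, layer="RNA", conditions=("tm",), times=(0, 1, 4, 8),
                      replicates=(1,), genes=None):
    """Small CountMatrix helper for hand-built examples.

    ``values`` is genes x samples with samples ordered as the full factorial
    (condition-major, then time, then replicate) grid.
    """
    design = so.make_design(layer, conditions, times, replicates)
    values = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                      columns=design.index)
    return so.CountMatrix(df, design)
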