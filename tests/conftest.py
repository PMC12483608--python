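import anndata as ad
import numpy as np
import pandas as pd
import pytest

import divscreen as ds


def make_adata(counts, gene_names=None, obs=None):
    """Tiny cells-by-genes AnnData with the counts layer tag."""
    counts = np.asarray(counts)
    n, g = counts.shape
    gene_names = gene_names or [f"g{j}" for j in range(g)]
    obs = obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(n)])
    obs.index.name = "cell_id"
    adata = ad.AnnData(
        X=counts,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene_id")),
    )
    adata.uns["layer_tag"] = "counts"
    return adata


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort, shared across tests."""
    cohort = ds.simulate_cohort(ds.SimConfig(seed=7))
    norm = ds.normalize_cp10k_log(cohort.adata)
    return cohort, norm


@pytest.fixture(scope="session")
def small_config():
    """Reduced problem size for repeated-simulation calibration checks."""
    return ds.SimConfig(
        n_patients=4, cells_per_patient_per_phase=40, n_genes=400, n_tfs=40
    )
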