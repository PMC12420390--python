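import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import anndata as ad

import patagium as pg


def make_dataset(counts, gene_ids=None, clusters=None, species="bat",
                 limb="FL", library="lib1", flags=None):
    """Build a CellDataset from a dense count array (cells x genes)."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(n_genes)]
    obs = pd.DataFrame({
        "species": species, "limb": limb, "stage": "E13", "library": library,
    }, index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell"))
    if clusters is not None:
        obs["cluster"] = list(clusters)
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    for flag, vals in (flags or {}).items():
        var[flag] = vals
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    return pg.CellDataset(adata)


def set_lognorm(dataset, values):
    """Install a normalized layer directly (for closed-form tests)."""
    dataset.adata.layers["lognorm"] = sp.csr_matrix(np.asarray(values, float))
    return dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic run shared across read-only tests."""
    spec = pg.SimulationSpec(n_cells_per_cluster=50, n_genes=1200, seed=11)
    dataset, truth = pg.generate_limb_dataset(spec)
    return spec, dataset, truth
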