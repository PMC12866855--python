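import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from oncotme.pipeline import PipelineConfig, run_all

# frozen seed of the shipped synthetic "ON/OFF" dataset used by the
# recovery tests; the full suite also exercises other seeds
SHIPPED_SEED = 1


def make_adata(counts, conditions=None, clusters=None, genes=None) -> AnnData:
    """Small AnnData from a dense cells x genes integer array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(
        {
            "condition": conditions if conditions is not None else ["ON"] * n,
            "cluster": clusters if clusters is not None else [0] * n,
        },
        index=[f"cell{i}" for i in range(n)],
    )
    var = pd.DataFrame(
        index=pd.Index(genes if genes is not None else
                       [f"g{j}" for j in range(g)], name="gene")
    )
    return AnnData(X=sp.csr_matrix(counts.astype(np.int32)), obs=obs, var=var)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Full pipeline on the shipped 2000-cells-per-condition dataset."""
    outdir = tmp_path_factory.mktemp("demo_run")
    results, manifest = run_all(PipelineConfig.demo(seed=SHIPPED_SEED), outdir)
    results["outdir"] = outdir
    return results
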