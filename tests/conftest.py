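import numpy as np
import pytest
import scipy.sparse as sp

import debrisem as dm


def make_matrix(counts, prefix="G"):
    """SparseCountMatrix from a dense genes x droplets array."""
    counts = np.asarray(counts)
    g, n = counts.shape
    return dm.SparseCountMatrix(
        gene_ids=[f"{prefix}{i:04d}" for i in range(g)],
        gene_names=[f"{prefix}{i:04d}" for i in range(g)],
        barcodes=[f"BC{j:04d}" for j in range(n)],
        counts=sp.csr_matrix(counts),
    )


@pytest.fixture(scope="session")
def default_scenario():
    """The default simulated experiment with its ground truth."""
    matrix, truth = dm.simulate_droplets(seed=7)
    return matrix, truth


@pytest.fixture(scope="session")
def default_run(default_scenario):
    """Full pipeline result on the default scenario.

    k is set to the number of simulated cell types plus one, so the ambient
    droplets that clear the cluster-set gene cutoff can form their own
    cluster next to the three cell types.
    """
    matrix, truth = default_scenario
    config = dm.RunConfig(k=truth.type_profiles.shape[0] + 1, seed=7)
    result = dm.run_pipeline(matrix, config)
    merged = result.score_table.merge(truth.droplets, on="barcode")
    return {"matrix": matrix, "truth": truth, "result": result, "table": merged}
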