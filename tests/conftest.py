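import numpy as np
import pandas as pd
import pytest

from cdc1niche import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bulk():
    params = synthetic.BulkSimParams(n_samples=40, n_genes=120, seed=7)
    return synthetic.gen_bulk_cohort(params)


@pytest.fixture
def tissue_table():
    return synthetic.gen_tissue(synthetic.TissueSimParams(seed=11))


@pytest.fixture
def st_matrix():
    params = synthetic.STSimParams(n_cells=1500, seed=13)
    return synthetic.gen_spatial_transcriptome(params)


def brute_force_mean_min_distance(src_xy: np.ndarray, dst_xy: np.ndarray) -> float:
    """O(n*m) oracle: mean over src points of min Euclidean distance to dst."""
    total = 0.0
    for p in src_xy:
        best = np.inf
        for q in dst_xy:
            d = np.hypot(p[0] - q[0], p[1] - q[1])
            if d < best:
                best = d
        total += best
    return total / len(src_xy)


def random_phenotyped_table(rng, n_cdc1, n_cd8, n_cd4, n_other=0, extent=500.0):
    n = n_cdc1 + n_cd8 + n_cd4 + n_other
    xy = rng.uniform(0, extent, size=(n, 2))
    pheno = (["cDC1"] * n_cdc1 + ["CD8T"] * n_cd8 + ["CD4T"] * n_cd4
             + ["other"] * n_other)
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "x_um": xy[:, 0], "y_um": xy[:, 1],
        "BATF3": 0.0, "CD3": 0.0, "CD8": 0.0,
        "phenotype": pheno,
    })
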