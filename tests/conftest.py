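import numpy as np
import pandas as pd
import pytest

from wlgenes import normalize, simdata
from wlgenes.weights import condition_vector


@pytest.fixture(scope="session")
def small_counts_dataset():
    """Counts-mode dataset with planted DE genes and one correlation block."""
    cfg = simdata.SimConfig(
        n_genes=300,
        seed=11,
        de_fraction=0.05,
        lfc_sd=2.5,
        dc_blocks=[(4, 0.0, 0.85)],
        blocks_are_de=True,
    )
    return simdata.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_logexpr(small_counts_dataset):
    """log2(normalized + 1) matrix + design + 0/1 labels of the fixture."""
    ds = small_counts_dataset
    normed, _ = normalize.normalize(ds.counts)
    X = normalize.log_transform(normed)
    y = condition_vector(ds.design, X.columns)
    return X, ds.design, y


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_design(n_control: int, n_stress: int) -> pd.DataFrame:
    ids = [f"S{j:02d}" for j in range(n_control + n_stress)]
    return pd.DataFrame(
        {
            "condition": ["control"] * n_control + ["stress"] * n_stress,
            "study": ["study1"] * (n_control + n_stress),
        },
        index=pd.Index(ids, name="sample_id"),
    )
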