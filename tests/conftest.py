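import numpy as np
import pandas as pd
import pytest

from amniotx.simulate import GROUP_IMMINENT, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (300 genes, 60 response genes) for fast unit tests."""
    cfg = SimConfig(n_genes=300, n_response_genes=60, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_group_mask(small_cohort):
    return (small_cohort.samples["group"] == GROUP_IMMINENT).to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_expr(values, genes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)
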