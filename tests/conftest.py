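import numpy as np
import pandas as pd
import pytest

from mirnome.io_formats import CountMatrix, SampleTable
from mirnome.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """A small cohort with planted eQTL and correlation structure."""
    cfg = SimConfig(
        seed=1234,
        n_mirnas=50,
        n_genes=300,
        n_snvs=100,
        eqtl_specs=[(0, 0, 0.6, 0.3), (1, 20, -0.5, 0.4)],
        corr_specs=[(i, 0, -1, 0.8) for i in range(5)]
        + [(i, 1, 1, 0.8) for i in range(5, 10)],
        trait_specs=[("birth_weight", 2, 150.0)],
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def two_group_meta():
    """16 term samples, 8 NORM vs 8 PE, balanced sexes."""
    samples = [f"S{i:02d}" for i in range(16)]
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "trimester": ["term"] * 16,
                "gestational_days": [265 + i for i in range(16)],
                "fetal_sex": ["XX", "XY"] * 8,
                "group": ["NORM"] * 8 + ["PE"] * 8,
            }
        ).set_index("sample_id")
    )


def nb_counts(rng, mu, alpha, shape):
    """Direct NB sampler used as an independent source in tests."""
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mu), shape)


@pytest.fixture()
def null_counts_16(two_group_meta):
    """2,000-feature null NB matrix over the 16-sample metadata."""
    rng = np.random.default_rng(7)
    mu = rng.uniform(100, 2000, 2000)
    counts = nb_counts(rng, mu[:, None], 0.1, (2000, 16))
    return CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"f{i:04d}" for i in range(2000)],
            columns=two_group_meta.sample_ids,
        )
    )
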