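import numpy as np
import pandas as pd
import pytest

import cafsig as cs


@pytest.fixture(scope="session")
def small_cohorts():
    """Three small cohorts with a strong planted signal (effect 2 SD)."""
    spec = cs.CohortSimSpec(
        n_cohorts=3, samples_per_cohort=30, n_genes=60,
        n_up=6, n_down=6, effect_size=2.0, seed=7,
    )
    return cs.simulate_cohorts(spec)


@pytest.fixture(scope="session")
def small_split():
    return cs.CohortGroupSplit(["C01"], ["C02"], ["C03"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_expression(rng, n_genes, n_samples):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    return pd.DataFrame(
        rng.normal(6, 2, size=(n_genes, n_samples)), index=genes, columns=samples
    )
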