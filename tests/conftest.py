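import numpy as np
import pandas as pd
import pytest

import traitscape as ts


@pytest.fixture(scope="session")
def default_cfg():
    return ts.default_config(seed=1)


@pytest.fixture(scope="session")
def std_table(default_cfg):
    table, truth = ts.simulate_trait_table(default_cfg)
    return table, truth


@pytest.fixture(scope="session")
def full_table(default_cfg, std_table):
    table, _ = std_table
    return ts.simulate_plasticity_shift(default_cfg, table)


@pytest.fixture(scope="session")
def scape(std_table):
    table, _ = std_table
    return ts.build_traitscape(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_trait_table(rng, n_rows=36, n_traits=9):
    """A random metadata-free trait table for numerical oracle tests."""
    data = rng.normal(size=(n_rows, n_traits))
    cols = [f"t{j}" for j in range(n_traits)]
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "strain_id", [f"s{i % 12:02d}" for i in range(n_rows)])
    df.insert(1, "replicate", [i // 12 + 1 for i in range(n_rows)])
    df.insert(2, "environment", "standard")
    return df
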