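import numpy as np
import pandas as pd
import pytest

import salinet as sn


@pytest.fixture(scope="session")
def small_survey():
    """A small simulated survey shared by read-only tests."""
    design = sn.GradientDesign(
        n_taxa=200,
        n_transects=2,
        sites_per_transect=12,
        sequencing_depth=20_000,
        seed=42,
    )
    table, meta, truth = sn.simulate_gradient(design)
    return design, table, meta, truth


@pytest.fixture()
def tiny_table():
    return pd.DataFrame(
        [[10, 0, 4], [5, 5, 4], [0, 15, 4]],
        index=["taxA", "taxB", "taxC"],
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
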