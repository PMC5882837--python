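import numpy as np
import pandas as pd
import pytest

from mirvar import normalize as norm
from mirvar import simulate


@pytest.fixture
def tiny_config():
    """Three hairpins, two groups x six replicates, deterministic layout."""
    return simulate.SimConfig(
        n_groups=2,
        n_replicates=6,
        n_hairpins=3,
        rng_seed=7,
    )


@pytest.fixture
def tiny_reference(tiny_config):
    return simulate.make_reference(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20180328)


@pytest.fixture
def random_count_matrix(rng):
    """50 miRNAs x 6 libraries, strictly positive counts, one group."""
    counts = pd.DataFrame(
        rng.integers(1, 2000, size=(50, 6)),
        index=[f"miR-{i}" for i in range(50)],
        columns=[f"L{j}" for j in range(6)],
    )
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
    return norm.CountMatrix(counts, groups)
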