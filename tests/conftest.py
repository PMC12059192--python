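import numpy as np
import pandas as pd
import pytest

from beetlenet import CommunityTable, default_config, generate_community


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """3 samples x 2 species hand-written table."""
    biomass = pd.DataFrame(
        [[1.5, 0.0], [0.0, 2.25], [3.0, 4.5]],
        index=["s1", "s2", "s3"],
        columns=["spA", "spB"],
    )
    habitat = pd.Series(
        ["clay_pit", "clay_pit", "mesotrophic"],
        index=biomass.index,
        name="habitat",
    )
    return CommunityTable(biomass=biomass, habitat=habitat)


@pytest.fixture(scope="session")
def small_community():
    """Deterministic two-habitat synthetic community for pair models."""
    cfg = default_config(
        n_species=12,
        n_samples_per_habitat={"gravel_pit": 160, "dystrophic": 160},
        cluster_size=4,
        within_cluster_rho=0.9,
        seed=99,
    )
    return generate_community(cfg)
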