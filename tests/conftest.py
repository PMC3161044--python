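import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import dpclust as dc


@pytest.fixture(scope="session")
def island_bases():
    """Two microsatellite island-model base populations (m = 0.003),
    shared by the simulator and clustering tests."""
    cfg = dc.IslandSimConfig()
    model = dc.IslandModel(cfg)
    return cfg, model, [model.run(seed=1000 + b) for b in range(2)]


@pytest.fixture
def two_pop_table():
    """Well-separated two-population microsatellite data (25 + 25)."""
    table, truth = dc.simulate_correlated(dc.microsat_scenario("uniform", 20), seed=7)
    return table, truth


@pytest.fixture
def tiny_snp():
    """Five individuals at two SNP loci — small enough for exhaustive
    posterior enumeration."""
    rng = np.random.default_rng(7)
    a1 = rng.integers(0, 2, (5, 2)).astype(np.int64)
    a2 = rng.integers(0, 2, (5, 2)).astype(np.int64)
    J = np.array([2, 2], dtype=np.int64)
    return a1, a2, J
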