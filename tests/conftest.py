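"""Shared fixtures: small hand-checkable tables and one cached scenario run."""

from __future__ import annotations

import numpy as np
import pytest

from mycassembly.tables import CommunityTable
from mycassembly.simulate import SimConfig, mixed_scenario


@pytest.fixture
def tiny_table() -> CommunityTable:
    """3 taxa x 2 samples with depths (10, 5) — hand-checkable."""
    return CommunityTable(
        counts=np.array([[6, 2, 2], [2, 3, 0]]),
        sample_ids=["sampleA", "sampleB"],
        taxon_ids=["t1", "t2", "t3"],
    )


@pytest.fixture(scope="session")
def null_base_table() -> CommunityTable:
    """20 samples x 50 taxa drawn multinomially from a lognormal pool.

    The base community for null-model calibration: its column sums define
    the regional pool, its rows the per-sample richness/total constraints.
    """
    rng = np.random.default_rng(42)
    pool = rng.lognormal(0, 1.5, 50)
    probs = pool / pool.sum()
    counts = np.vstack([rng.multinomial(500, probs) for _ in range(20)])
    return CommunityTable(counts, [f"s{i:02d}" for i in range(20)],
                          [f"t{j:02d}" for j in range(50)])


@pytest.fixture(scope="session")
def mixed_run():
    """Mixed-process scenario at the default seed, shared across tests."""
    cfg = SimConfig(seed=0)
    table, meta = mixed_scenario(cfg)
    return cfg, table, meta
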