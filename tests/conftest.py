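import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from gslab import simulate_trial


@pytest.fixture(scope="session")
def fs_trial():
    """A small but structured full-sib trial shared across tests."""
    return simulate_trial(
        "full-sib",
        seed=7,
        n_families=12,
        offspring_per_family=18,
        n_markers=3_000,
        n_qtl=120,
        n_parents=20,
        blocks_per_site=4,
    )


@pytest.fixture(scope="session")
def hs_trial():
    """A small open-pollinated half-sib trial."""
    return simulate_trial(
        "half-sib",
        seed=9,
        n_families=10,
        offspring_per_family=21,
        n_markers=2_000,
        n_qtl=100,
        pollen_pool_size=80,
        blocks_per_site=4,
    )
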