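import numpy as np
import pytest

from combiscreen import (
    FilterConfig,
    LatentParams,
    PartLibrary,
    SimConfig,
    simulate_screen,
)
from combiscreen.scoring import (
    filter_outlier_umis,
    group_and_normalize,
    score_activation_screen,
    score_toxicity_screen,
)
from combiscreen.simulate import drop_controls


@pytest.fixture(scope="session")
def library():
    return PartLibrary.default(n_ads=22, n_pfs=3, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A quick bipartite screen for module-level plumbing tests."""
    cfg = SimConfig(
        arity=2,
        n_cells=60_000,
        read_depth=150_000,
        targets=("EPCAM",),
        n_replicates=2,
        seed=11,
    )
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def full_sim():
    """Bipartite screen at study scale (10^6 cells, 10^6 reads/condition)."""
    cfg = SimConfig(arity=2, n_cells=1_000_000, read_depth=1_000_000, seed=1)
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def full_scores(full_sim):
    """Activation and toxicity scores recovered from the full simulation."""
    cfg = FilterConfig()
    table = drop_controls(full_sim.counts)
    grouped = group_and_normalize(filter_outlier_umis(table, cfg), cfg)
    activation = score_activation_screen(grouped, full_sim.mfi, cfg)
    toxicity = score_toxicity_screen(table, FilterConfig(umi_prefix_length=0))
    return activation, toxicity
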