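import numpy as np
import pytest

from gbsmap.simcross import SimConfig, simulate_cross


@pytest.fixture(scope="session")
def clean_lg():
    """One 100 cM linkage group, complete error-free calls, n = 184."""
    cfg = SimConfig(
        n_offspring=184, lg_lengths=(100.0,), markers_per_lg=(60,),
        type_proportions=((0.5, 0.2, 0.3, 0.0, 0.0),),
        error_rate=0.0, missing_rate=0.0, seed=11,
    )
    return simulate_cross(cfg, with_counts=False)


@pytest.fixture(scope="session")
def noisy_cross():
    """Three small LGs with read counts at depth 30 and 1% read errors."""
    cfg = SimConfig(
        n_offspring=150, lg_lengths=(90.0, 80.0, 70.0),
        markers_per_lg=(30, 30, 30),
        type_proportions=((0.5, 0.2, 0.2, 0.05, 0.05),),
        mean_depth=30.0, seed=8,
    )
    return simulate_cross(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
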