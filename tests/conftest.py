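import numpy as np
import pytest

from soilregimes import CRMParams
from soilregimes.fitting import PAPER_TIME_GRID_DAYS

# the three regime-typical simulated scenarios used throughout the suite:
# acidic-death-like, nutrient-limiting, resurgent growth
SCENARIOS = [
    CRMParams(x0_tilde=0.01, C0_tilde=0.005, A0=2.0, A0c=2.0, gamma=4.0),
    CRMParams(x0_tilde=0.1, C0_tilde=0.05, A0=2.0, A0c=2.0, gamma=4.0),
    CRMParams(x0_tilde=0.001, C0_tilde=2.0, A0=2.0, A0c=2.0, gamma=4.0),
]


@pytest.fixture(scope="session")
def scenarios():
    return SCENARIOS


@pytest.fixture(scope="session")
def day_grid():
    return np.linspace(0.0, 4.0, 41)


@pytest.fixture(scope="session")
def paper_grid():
    return PAPER_TIME_GRID_DAYS


@pytest.fixture(scope="session")
def small_count_table():
    """Reduced-size synthetic count table shared by abundance/enrichment tests."""
    from soilregimes.synthetic import SynthConfig, synth_count_table

    cfg = SynthConfig(seed=11, n_soils=4, n_asv=600, mean_depth=25000)
    table, truth = synth_count_table(cfg)
    return cfg, table, truth
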