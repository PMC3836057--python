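import numpy as np
import pytest

import trioscreen as ts


@pytest.fixture(scope="session")
def study_replicate():
    """One scenario-1 replicate (panel + phenotypes) shared across tests."""
    cfg = ts.ScenarioConfig.for_scenario(1)
    panel, phen = ts.simulate_study(800, 0.3, cfg, seed=1234)
    return panel, phen


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
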