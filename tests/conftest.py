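import numpy as np
import pytest

import connrel as cr


@pytest.fixture(scope="session")
def default_panel():
    """Complete balanced panel at the study's default design and truth:
    K=10, J=4, I=12, (sigma3^2, sigma2^2, sigma0^2) = (0.04, 0.01, 0.10)."""
    cfg = cr.SimulationConfig(n_edges=300, seed=42)
    panel, truth = cr.simulate_edge_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def tiny_integer_panel():
    """K=2, J=2, I=2 panel with small integer values for hand checking."""
    values = np.array(
        [[[[1.0], [3.0]], [[2.0], [6.0]]],
         [[[5.0], [7.0]], [[4.0], [8.0]]]])
    return cr.EdgeObservationPanel(values)


@pytest.fixture(scope="session")
def small_timeseries_collection():
    cfg = cr.SimulationConfig(n_rois=12, seed=7, n_timepoints=200)
    coll, panel, truth = cr.simulate_timeseries_panel(cfg)
    return cfg, coll, panel, truth
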