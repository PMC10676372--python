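import numpy as np
import pytest

from sdlamina import synthetic_cortex as sc


@pytest.fixture(scope="session")
def partial_session():
    """One partial SD (stop 900 um) with spiking, shared across tests."""
    cfg = sc.SessionConfig(
        duration_s=160.0,
        sd_plans=[sc.SDPlan(onset_top_s=70.0, stop_depth_um=900.0)],
        spikes=True,
    )
    rec, _, truth = sc.simulate_laminar_session(cfg, seed=11)
    return rec, truth


@pytest.fixture(scope="session")
def full_session():
    """One full SD (stop 1600 um), no spiking."""
    cfg = sc.SessionConfig(
        duration_s=160.0,
        sd_plans=[sc.SDPlan(onset_top_s=70.0, stop_depth_um=1600.0)],
        spikes=False,
    )
    rec, _, truth = sc.simulate_laminar_session(cfg, seed=12)
    return rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
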