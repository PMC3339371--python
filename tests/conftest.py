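import numpy as np
import pytest

from ventmech import SimConfig, segment_breaths, simulate_breath


def make_breath(
    e=30.0,
    r=5.0,
    peep=10.0,
    tidal_volume=0.5,
    intra_breath_slope=0.0,
    flow_shape="square",
    noise_sd_paw=0.0,
    noise_sd_flow=0.0,
    seed=0,
):
    """One segmented breath from the simulator with constant baseline elastance."""
    cfg = SimConfig(
        e_peep_profile=lambda p: e,
        intra_breath_slope=intra_breath_slope,
        r_lung=r,
        tidal_volume=tidal_volume,
        flow_shape=flow_shape,
        noise_sd_paw=noise_sd_paw,
        noise_sd_flow=noise_sd_flow,
        seed=seed,
    )
    rec, truth = simulate_breath(cfg, peep, rng=np.random.default_rng(seed))
    breaths = segment_breaths(rec)
    assert len(breaths) == 1
    return breaths[0], truth


@pytest.fixture
def noiseless_breath():
    """Noiseless square-flow breath: E=30, R=5, PEEP=10, Vt=0.5."""
    breath, _ = make_breath()
    return breath


@pytest.fixture
def ramp_breath():
    """Noiseless breath whose elastance falls 40 -> 25 cmH2O/l within the breath.

    Square flow 0.5 l/s means V = 0.5 t, so a volume slope of -30 cmH2O/l
    per litre yields E(t) = 40 - 15 t over the 1 s inspiration.
    """
    breath, truth = make_breath(e=40.0, intra_breath_slope=-30.0)
    return breath, truth
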