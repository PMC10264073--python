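import numpy as np
import pytest

import phasetrack as pt


@pytest.fixture(scope="session")
def acq():
    return pt.AcquisitionParams(frame_interval=0.03)


@pytest.fixture(scope="session")
def two_state_tracks(acq):
    """Synthetic condensed-phase tracks from the two-state diffusive model
    at the reference parameters (D_c = 0.0127, D_m = 0.167 um^2/s,
    P_mc = 0.828, P_cm = 0.038 per 30 ms frame)."""
    rates = pt.SwitchRates(P_cm=0.038, P_mc=0.828, per="frame")
    return pt.simulate_hmm_tracks(0.0127, 0.167, rates, n_tracks=2000,
                                  mean_steps=10, acquisition=acq, seed=42)


@pytest.fixture(scope="session")
def psd_scene(acq):
    """Small two-phase condensate scene with enrichment consistent with the
    kinetic relation for its own parameters."""
    geom = pt.DiskRegions([[3.0, 3.0, 0.8], [7.0, 7.0, 0.8], [7.0, 2.5, 0.7]])
    rates = pt.SwitchRates(P_cm=0.038, P_mc=0.828, per="frame")
    ef = pt.ef_from_kinetics(0.47, 0.167, rates.mobile_ratio)
    gt, table = pt.simulate_condensate_scene(
        geom, box=(10.0, 10.0), sigma_c=0.3, ef=ef, D_d=0.47, D_m=0.167,
        rates=rates, n_frames=15_000, acquisition=acq, seed=7)
    return geom, ef, gt, table
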