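import numpy as np
import pytest

from glucoflow import (
    ASLGroundTruth,
    CESTGroundTruth,
    SaturationSchedule,
    StimDesign,
    simulate_asl_session,
    simulate_cest_session,
)


@pytest.fixture(scope="session")
def schedule() -> SaturationSchedule:
    return SaturationSchedule()


@pytest.fixture(scope="session")
def design() -> StimDesign:
    return StimDesign()


@pytest.fixture()
def clean_cest_session():
    """Noise- and drift-free CEST session on a small grid, with truth."""
    truth = CESTGroundTruth(noise_sd=0.0, drift_slope=0.0)
    return simulate_cest_session(truth=truth, seed=0, grid_shape=(4, 4))


@pytest.fixture()
def clean_asl_session():
    """Noise-free resting pCASL session (no active voxels), with truth."""
    truth = ASLGroundTruth(cbf_true=150.0, noise_sd=0.0, active_mask=None)
    return simulate_asl_session(truth=truth, seed=0, grid_shape=(6, 6))
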