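import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tempopac import synthetic as syn
from tempopac import tpac as tp

FS = 300.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def default_truth():
    """Study-condition ground truth: alpha 10 Hz, gamma 60 Hz, m=0.9, 5 dB."""
    return syn.PacGroundTruth(seed=7)


@pytest.fixture(scope="session")
def coupled_epoch(default_truth):
    t, x = syn.generate_pac_epoch(default_truth, duration_s=4.0, fs_hz=FS)
    return t, x


@pytest.fixture(scope="session")
def noiseless_epoch():
    truth = syn.PacGroundTruth(snr_db=None, seed=3)
    t, x = syn.generate_pac_epoch(truth, duration_s=4.0, fs_hz=FS)
    return truth, t, x


@pytest.fixture(scope="session")
def tpac_config():
    return tp.TpacConfig()


@pytest.fixture(scope="session")
def gamma_band_kernel():
    """Filter kernel for the sub-band centered on 60 Hz (48-72 Hz)."""
    return tp.design_bandpass(48.0, 72.0, FS)


@pytest.fixture(scope="session")
def behavior_table():
    return syn.generate_behavior(syn.BehaviorGroundTruth(seed=11))
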