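import numpy as np
import pytest

from bbbdce import (
    AcquisitionParams,
    AifParams,
    DynamicSeries,
    PhantomConfig,
    make_aif,
    make_phantom,
    spgr_signal,
)


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def default_aif(acq):
    return make_aif(AifParams(), acq.time_s)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Noise- and drift-free phantom with the instantaneous vascular model."""
    cfg = PhantomConfig(noise_sd=0.0, drift_pct_per_min=0.0, seed=7)
    return cfg, make_phantom(cfg)


@pytest.fixture(scope="session")
def dispersed_phantom():
    """Noise-free phantom whose vascular term is a dispersed residue channel,
    carrying a recoverable flow truth."""
    cfg = PhantomConfig(
        noise_sd=0.0, drift_pct_per_min=0.0, vascular_model="dispersed", seed=7
    )
    return cfg, make_phantom(cfg)


def synth_voxel_signal(conc_mM, t10_ms, m0, acq: AcquisitionParams):
    """SPGR signal-time course for a known concentration curve (helper used
    by round-trip tests)."""
    r1 = 1000.0 / t10_ms + acq.relaxivity_r1 * np.asarray(conc_mM)
    return spgr_signal(m0, 1000.0 / r1, acq.flip_deg, acq.tr_ms)


def make_series(signal_2d, acq: AcquisitionParams) -> DynamicSeries:
    """Wrap an (n_vox, n_frames) signal array as a DynamicSeries on a
    (n_vox, 1, 1) grid."""
    sig = np.asarray(signal_2d, dtype=float)
    return DynamicSeries(signal=sig[:, None, None, :].transpose(0, 1, 2, 3).reshape(
        sig.shape[0], 1, 1, sig.shape[1]), params=acq)
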