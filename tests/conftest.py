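import numpy as np
import pytest

from perfsyn.maps import DeconvolutionConfig, compute_all_maps
from perfsyn.phantom import AcquisitionParams, build_phantom, generate_cohort
from perfsyn.preprocess import build_dataset


@pytest.fixture(scope="session")
def noiseless_acq():
    return AcquisitionParams(n_frames=64, grid=(4, 32, 32), noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_acq):
    return build_phantom(seed=11, acq=noiseless_acq)


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_phantom):
    return compute_all_maps(noiseless_phantom, cfg=DeconvolutionConfig(svd_threshold_fraction=0.0))


@pytest.fixture(scope="session")
def tiny_dataset():
    """8-patient small-grid cohort -> tmax dataset (train/val/test)."""
    cohort = generate_cohort(8, seed=21)
    vols = {
        pid: (ph.signal, compute_all_maps(ph).tmax, ph.brain_mask)
        for pid, ph in cohort.items()
    }
    return build_dataset(vols, "tmax", fractions=(0.5, 0.25, 0.25), seed=4)
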