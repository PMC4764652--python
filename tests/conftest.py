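import numpy as np
import pytest

from osteoquant import synth
from osteoquant.geometry import q_chi_map


@pytest.fixture(scope="session")
def geometry():
    return synth.default_geometry()


@pytest.fixture(scope="session")
def maps(geometry):
    return q_chi_map(geometry, (384, 384))


@pytest.fixture(scope="session")
def noiseless_wt_sequence():
    """Short noiseless WT loading sequence with its truth table."""
    return synth.gen_saxd_sequence(
        synth.WT,
        noise=synth.NoiseModel(photon_scale=np.inf, detector_sd=0.0, seed=0),
        n_frames=6,
        return_components=True,
    )


@pytest.fixture(scope="session")
def noisy_wt_sequence():
    """WT sequence at the default photon scale (Poisson + detector noise)."""
    return synth.gen_saxd_sequence(
        synth.WT, noise=synth.NoiseModel(seed=42), n_frames=10
    )
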