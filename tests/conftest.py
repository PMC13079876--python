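import numpy as np
import pytest

import fuccitrack as ft


@pytest.fixture(scope="session")
def noiseless_model():
    return ft.CycleModel(noise_sigma=0.0, bleaching=0.0)


@pytest.fixture(scope="session")
def reference(noiseless_model):
    """Reference curve built from one noiseless full-cycle track."""
    track, _ = ft.simulate_fucci_track(noiseless_model, 0.0, 101)
    return ft.build_reference_curve([track])


@pytest.fixture(scope="session")
def small_movie():
    """A small rendered movie with ground truth, shared across tests."""
    model = ft.CycleModel(seed=3)
    cfg = ft.MovieConfig(
        frames=12, height=128, width=128, n_nuclei=4, target_snr=4.0,
        tubulin_on=True, seed=3,
    )
    return ft.simulate_movie(model, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# make sibling helper modules (oracles.py) importable under rootdir-less runs
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
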