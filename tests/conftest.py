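import numpy as np
import pytest

from acnn.io_ct import CtVolume
from acnn.synthetic import PhantomConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def unit_volume():
    """A 200^3-ish deterministic ramp volume with unit spacing at origin 0."""
    vox = np.arange(120**3, dtype=np.float64).reshape(120, 120, 120) % 97
    return CtVolume(vox, origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0),
                    series_id="unit")


@pytest.fixture(scope="session")
def small_dataset():
    """A small phantom cohort shared across tests (8 scans, fixed seed)."""
    return generate_dataset(PhantomConfig(n_scans=8, seed=5))
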