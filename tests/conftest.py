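import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    """A fast phantom: small tissue, few cells, few sections."""
    from pepatlas.synthetic_data import PhantomConfig

    return PhantomConfig(
        seed=7,
        tissue_axes_um=(120.0, 80.0),
        n_cells=12,
        n_sections=3,
    )


@pytest.fixture
def small_dataset():
    """Three-pixel MSI dataset with simple spectra."""
    from pepatlas.msi_io import MSIDataset

    mz = np.array([600.0, 1000.5, 1500.0])
    return MSIDataset(
        coordinates=[(0, 0), (1, 0), (0, 1)],
        spectra=[
            (mz.copy(), np.array([2.0, 3.0, 5.0])),
            (mz.copy(), np.array([1.0, 0.0, 4.0])),
            (mz.copy(), np.array([0.5, 7.0, 0.25])),
        ],
    )
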