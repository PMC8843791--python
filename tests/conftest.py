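import numpy as np
import pytest

from fusionclass import PhantomSpec, generate_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def disk_image():
    """Bright disk (r=30) on a dark background, noiseless."""
    yy, xx = np.mgrid[:128, :128]
    mask = (yy - 64) ** 2 + (xx - 64) ** 2 <= 30**2
    return 0.1 + 0.8 * mask.astype(np.float64)


@pytest.fixture(scope="session")
def spiculated_image():
    """Six deep spiculations (amplitude 0.4 r) on the same grid."""
    yy, xx = np.mgrid[:128, :128]
    rr = np.hypot(yy - 64.0, xx - 64.0)
    theta = np.arctan2(yy - 64.0, xx - 64.0)
    boundary = 22.0 * (1.0 + 0.4 * np.sin(6 * theta))
    return 0.1 + 0.8 * (rr <= boundary).astype(np.float64)


@pytest.fixture(scope="session")
def benign_pair():
    return generate_pair(
        PhantomSpec(label="benign", spiculation_amplitude=0.02), seed=11)


@pytest.fixture(scope="session")
def malignant_pair():
    return generate_pair(
        PhantomSpec(label="malignant", spiculation_amplitude=0.35,
                    spiculation_lobes=7), seed=12)
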