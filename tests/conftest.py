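import numpy as np
import pytest
from hypothesis import settings

import necrovol as nv

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

#: phantom calibration used throughout the suite (50 µm/px keeps a whole
#: cervix cross-section inside a 320 px canvas)
PHANTOM_GEOM = nv.StackGeometry(pixel_size_mm=0.05)


@pytest.fixture(scope="session")
def geom() -> nv.StackGeometry:
    return PHANTOM_GEOM


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, jitter-free well-posed phantom (exact-recovery oracle)."""
    cfg = nv.well_posed_config(seed=11, noisy=False, jittered=False)
    return nv.generate_phantom(cfg, PHANTOM_GEOM)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Moderate staining noise and background specks, no jitter."""
    cfg = nv.well_posed_config(seed=12, noisy=True, jittered=False)
    return nv.generate_phantom(cfg, PHANTOM_GEOM)


@pytest.fixture(scope="session")
def jittered_phantom():
    """Full study conditions: noise plus rigid jitter up to 20 px / 10°."""
    cfg = nv.well_posed_config(seed=13)
    return nv.generate_phantom(cfg, PHANTOM_GEOM)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = np.count_nonzero(a) + np.count_nonzero(b)
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom
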