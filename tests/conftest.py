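import numpy as np
import pytest

from toothstage import phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, clutter-free stage-F phantom: two-valued image + exact mask."""
    spec = phantom.PhantomSpec(stage="F", clutter_level=0.0,
                               impulse_noise_fraction=0.0, contrast=1.0,
                               seed=7)
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def small_dataset():
    """12 phantoms (one per stage x cohort), default noise settings."""
    return phantom.generate_dataset(1, seed=42)
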