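import numpy as np
import pytest

from giftdiam.bench import BENCH_PARAMS
from giftdiam.synthgen import SyntheticImageSpec, generate_disordered


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def disordered_w20():
    """One mid-sized disordered synthetic image with known 20 px line width."""
    spec = SyntheticImageSpec(
        kind="disordered", width_px=20, image_size=(512, 512), seed=42
    )
    return generate_disordered(spec), spec


@pytest.fixture(scope="session")
def bench_params():
    return BENCH_PARAMS
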