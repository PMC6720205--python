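import numpy as np
import pytest

from embryogan.phantom import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def small_phantom_set():
    """A small mixed-class phantom set at desk scale (32 px)."""
    return generate_dataset([6, 6, 6], base_seed=42, config=PhantomConfig(image_size=32))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
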