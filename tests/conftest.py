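import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20180629)


def random_rgb(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
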