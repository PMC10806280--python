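import numpy as np
import pytest

from marrowseg.volumes import LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_mask(rng, shape=(6, 6, 6), p=0.3):
    return LabelMask((rng.random(shape) < p).astype(np.uint8), (2.2, 2.2, 4.5))
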