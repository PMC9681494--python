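import numpy as np
import pytest

from drdetect.synthetic import SynthSpec, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dr_image():
    """One synthetic image with a known lesion mix."""
    spec = SynthSpec(lesion_counts={"MA": 3, "EX": 2, "HEM": 1}, rng_seed=5)
    image, masks, label = generate_image(spec)
    return spec, image, masks, label


@pytest.fixture
def healthy_image():
    spec = SynthSpec(rng_seed=11)
    image, masks, label = generate_image(spec)
    return spec, image, masks, label
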