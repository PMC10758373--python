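import numpy as np
import pytest
from hypothesis import settings

from sonodistill import SyntheticSpec, generate_dataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small 6-class synthetic dataset shared across tests (16x16,
    4 patients and 12 images per class)."""
    spec = SyntheticSpec(
        images_per_class=12, patients_per_class=4, image_size=(16, 16), seed=11
    )
    samples, manifest = generate_dataset(spec)
    return spec, samples, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
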