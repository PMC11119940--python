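import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 5-class long-tailed synthetic dataset shared across tests."""
    from pestnet import SyntheticSpec, generate_synthetic

    spec = SyntheticSpec(num_classes=5, images_per_class_max=30,
                         image_size=64, seed=7)
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def eight_image_manifest(tiny_dataset):
    """Two images from each of four classes — the memorisation fixture."""
    labels = tiny_dataset.labels
    idx = [int(np.where(labels == c)[0][k]) for c in range(4) for k in range(2)]
    return tiny_dataset.subset(idx)
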