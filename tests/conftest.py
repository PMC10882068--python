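import numpy as np
import pytest

from qmpa.synthetic import FeatureSpec, PhantomSpec, make_feature_dataset, make_phantom_images


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantoms():
    """A small, fast phantom batch: 3 classes x 8 images at side 16."""
    spec = PhantomSpec(class_counts=(8, 8, 8), image_side=16, seed=3)
    images, labels, manifest = make_phantom_images(spec)
    return images, labels, manifest


@pytest.fixture(scope="session")
def separable_features():
    """Well-separated synthetic features (5 informative of 30)."""
    spec = FeatureSpec(n_per_class=60, n_classes=3, d=30, n_informative=5,
                       class_sep=3.0, seed=11)
    return make_feature_dataset(spec)
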