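import numpy as np
import pytest

from mixgpcm.parameters import ClassParams, ModelParameters, RatingScale


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_two_class():
    """2 items, 2 categories, 2 classes — small enough for full enumeration."""
    return ModelParameters(
        scale=RatingScale(2),
        classes=[
            ClassParams(np.array([[-0.7], [0.4]]), trait_sd=1.0),
            ClassParams(np.array([[1.1], [-0.2]]), trait_sd=0.6),
        ],
        weights=np.array([0.6, 0.4]),
        discriminations=np.array([1.0, 1.3]),
    )


@pytest.fixture
def uniform_item_model():
    """Single class, one 4-category item with all thresholds zero."""
    return ModelParameters(
        scale=RatingScale(4),
        classes=[ClassParams(np.zeros((1, 3)), trait_sd=1.0)],
        weights=np.array([1.0]),
        discriminations=np.array([1.0]),
    )
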