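import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=200)
settings.load_profile("deterministic")


def make_disk_image(
    shape=(256, 256), centers=((128, 128),), radius=30, fg=200.0, bg=10.0
):
    """Flat disks on a flat background — the simplest detectable blobs."""
    img = np.full(shape, bg, dtype=np.float64)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img[np.hypot(yy - cy, xx - cx) <= radius] = fg
    return img


@pytest.fixture(scope="session")
def trained_model():
    """Classifier trained on single-structure synthetic fixtures.

    Session-scoped: the training corpus (8 rosette-only plus 8 focus-only
    tissues) is the expensive part shared by the end-to-end tests.
    """
    from rosettequant.classify import train_classifier
    from rosettequant.synthetic import synthetic_training_set

    vectors, labels = synthetic_training_set(n_per_class=8, seed=42)
    assert labels.count("rosette") >= 2 and labels.count("focus") >= 2
    return train_classifier(vectors, labels, seed=0)


@pytest.fixture()
def zero_model():
    """Indifferent classifier (p = 0.5 everywhere) for plumbing tests."""
    from rosettequant.classify import ClassifierModel

    return ClassifierModel(
        weights=np.zeros(8), intercept=0.0, center=np.zeros(8), scale=np.ones(8)
    )
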