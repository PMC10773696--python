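import numpy as np
import pytest

from endoframe import fixtures
from endoframe.frame import Frame, LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def class_specs():
    return fixtures.default_class_specs(4)


@pytest.fixture(scope="session")
def small_frame(class_specs):
    return fixtures.make_frame(class_specs[0], 48, 48, seed=0)


@pytest.fixture(scope="session")
def textured_frame(class_specs):
    return fixtures.make_frame(class_specs[1], 64, 64, seed=1)


@pytest.fixture(scope="session")
def reflected(class_specs):
    """(frame with 3 injected highlights, ground-truth mask)."""
    base = fixtures.make_frame(class_specs[2], 64, 64, seed=2)
    return fixtures.inject_reflections(base, 3, seed=3)


@pytest.fixture(scope="session")
def tiny_dataset(class_specs):
    """Small imbalanced labelled dataset (4 classes, 34 frames)."""
    imbalance = fixtures.ImbalanceSpec(
        {class_specs[0].name: 4, class_specs[1].name: 8,
         class_specs[2].name: 10, class_specs[3].name: 12}
    )
    return fixtures.make_dataset(class_specs, imbalance, seed=5, height=48, width=48)


@pytest.fixture(scope="session")
def separable_features():
    """Linearly separable 3-class feature matrix in [0, 1]."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.2, 0.2, 0.8], [0.8, 0.2, 0.2], [0.5, 0.8, 0.5]])
    x, y = [], []
    for c, center in enumerate(centers):
        x.append(np.clip(center + rng.normal(0, 0.03, size=(30, 3)), 0, 1))
        y.extend([c] * 30)
    return np.vstack(x), np.array(y)


def make_solid_frame(color, h=48, w=48, label="solid"):
    px = np.full((h, w, 3), color, dtype=np.uint8)
    return Frame(px, id=f"solid_{color}", label=label)
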