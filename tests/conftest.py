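"""Shared fixtures: synthetic datasets and the two trained CNNs.

Training the small CNNs dominates suite runtime, so the binary (eardrum
present/absent) model and the 3-class view model are trained once per session
on generator output and shared by every test that needs a real classifier.
"""

from __future__ import annotations

import numpy as np
import pytest

from lucid.nn import TrainConfig
from lucid.synthetic import generate_shapes_dataset, generate_view_dataset
from lucid.view import train_view_classifier


@pytest.fixture(scope="session")
def shapes_data():
    """Training split of the eardrum-present/absent shapes benchmark."""
    return generate_shapes_dataset(200, seed=42)


@pytest.fixture(scope="session")
def shapes_testset():
    """Held-out shapes images with ground-truth masks."""
    return generate_shapes_dataset(40, seed=777)


@pytest.fixture(scope="session")
def binary_model(shapes_data):
    """Binary background/eardrum CNN trained to high accuracy on shapes."""
    images, labels, _ = shapes_data
    model = train_view_classifier(
        images, labels, TrainConfig(seed=0, epochs=30, restarts=3), n_classes=2
    )
    return model


@pytest.fixture(scope="session")
def view_model():
    """3-class (none/partial/full) view classifier."""
    images, labels = generate_view_dataset(300, seed=3)
    return train_view_classifier(
        images, labels, TrainConfig(seed=0, epochs=25, restarts=3), n_classes=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
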