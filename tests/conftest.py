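"""Shared fixtures: tiny seeded synthetic datasets and trained models.

Training fixtures are session-scoped and deliberately small: they exist
to exercise the full training/inference paths, not to reach the accuracy
of the full-scale protocol (that is the acceptance suite's job).
"""

from __future__ import annotations

import numpy as np
import pytest

from embryostage.synthgen import generate_cls_dataset, generate_seg_dataset


@pytest.fixture(scope="session")
def seg_data():
    """24 synthetic (image, mask) pairs at 32 px with some noise."""
    items, manifest = generate_seg_dataset(24, size=32, noise_rate=0.25, seed=101)
    images = np.stack([im for im, _, _ in items])
    masks = np.stack([m for _, m, _ in items])
    return images, masks, manifest


@pytest.fixture(scope="session")
def cls_data():
    """10 clean extracted images per stage at 48 px."""
    images, labels, manifest = generate_cls_dataset(
        10, size=48, noise_rate=0.0, seed=202
    )
    return images, labels, manifest


@pytest.fixture(scope="session")
def trained_seg(seg_data):
    from embryostage.segnet import SegNetConfig, SegTrainConfig, train_segmenter

    images, masks, _ = seg_data
    return train_segmenter(
        images,
        masks,
        SegTrainConfig(epochs=8, batch_size=8, learning_rate=0.002),
        SegNetConfig(base_features=8, depth=2, dropout_rate=0.1),
        seed=33,
    )


@pytest.fixture(scope="session")
def trained_cls(cls_data):
    from embryostage.stagenet import ClsNetConfig, ClsTrainConfig, train_classifier

    images, labels, _ = cls_data
    return train_classifier(
        images,
        labels,
        ClsTrainConfig(epochs=16, batch_size=16, learning_rate=0.001),
        ClsNetConfig(base_width=8, input_size=48),
        seed=44,
    )
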