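"""Shared fixtures: synthetic image sets, planted tables, trained tinycnn."""

from __future__ import annotations

import numpy as np
import pytest

import lesionfuse as lf
from lesionfuse.backbones import (
    FineTuneConfig,
    build_backbone,
    build_finetune_head,
    fine_tune,
)


@pytest.fixture(scope="session")
def blob_set_2class():
    """Two-class blob image set: 50/class, 32 px, near-separable by design."""
    return lf.make_image_set(2, 50, 32, 1)


@pytest.fixture(scope="session")
def planted_table():
    """The planted selection fixture: 3 informative + 9 noise columns,
    class separation 4, 200 samples, 3 classes."""
    return lf.make_feature_table(200, 3, 9, 3, 4.0, 5)


@pytest.fixture(scope="session")
def trained_tinycnn(blob_set_2class):
    """tinycnn fine-tuned 3 epochs on the blob fixture, with its split.

    Learning rate 1e-2 — the from-scratch RMSProp rate appropriate for
    the small fixture backbone (the 1e-4 default is the deep-transfer
    recipe).
    """
    model, spec = build_backbone("tinycnn", seed=0)
    model = build_finetune_head(model, spec, 2, seed=0)
    cfg = FineTuneConfig(seed=0, learning_rate=1e-2)
    model, split = fine_tune(model, blob_set_2class, cfg)
    return model, spec, split


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_image(rng, h=5, w=7):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
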