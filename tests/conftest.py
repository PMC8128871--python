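"""Shared fixtures: small synthetic datasets and a small trained pipeline.

Unit tests run on deliberately small instances (tens of patches, small
vocabularies); the full-scale study conditions live in test_acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pytest

from trapvision.annotations import DEFAULT_TAXONOMY
from trapvision.runner import ModelConfig, train_model
from trapvision.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_train_records():
    return generate_dataset(
        {c: 40 for c in DEFAULT_TAXONOMY}, decay=0.0, rng_seed=11, dataset_tag="Lab0d"
    )


@pytest.fixture(scope="session")
def small_test_records():
    return generate_dataset(
        {c: 15 for c in DEFAULT_TAXONOMY}, decay=0.0, rng_seed=12, dataset_tag="Lab0d"
    )


@pytest.fixture(scope="session")
def small_pipeline(small_train_records):
    """Greyscale kdtree pipeline with a 64-word dictionary, trained once."""
    mc = ModelConfig(
        model_id="unit",
        vocsize=64,
        colour="greyscale",
        quantizer="kdtree",
        pooling="none",
        seed=0,
    )
    return train_model(mc, small_train_records)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
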