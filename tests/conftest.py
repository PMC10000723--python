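"""Shared fixtures. The desk-scale GAN run is session-scoped because the
25-epoch training is by far the most expensive thing the suite does; every
test that needs a trained generator shares it."""

from __future__ import annotations

import numpy as np
import pytest

import spinefs as sf
from spinefs.config import (PhantomConfig, build_training_dataset,
                            make_phantom_dataset)
from spinefs.gan_core import TrainConfig, make_generator_from_checkpoint, train


@pytest.fixture(scope="session")
def phantom_scene():
    return sf.make_phantom(11, pathology_spec=[("bone_marrow_abnormality", 0.5),
                                               ("vertebral_fracture", 1)])


@pytest.fixture(scope="session")
def desk_scale_run():
    """200 slice pairs (20 phantoms x 10 sagittal slices, 64 x 64), 25 epochs.

    Returns the checkpoint, the per-epoch history, the three held-out phantom
    datasets, and the reconstructed generator.
    """
    cfg = PhantomConfig()
    train_sets = make_phantom_dataset(7, cfg, cfg.n_train)
    test_sets = make_phantom_dataset(7, cfg, cfg.n_test, first_id=cfg.n_train)
    dataset = build_training_dataset(train_sets)
    assert len(dataset) == 200
    checkpoint, history = train(dataset, TrainConfig(epochs=25, seed=1))
    return {
        "checkpoint": checkpoint,
        "history": history,
        "test_sets": test_sets,
        "generator": make_generator_from_checkpoint(checkpoint),
    }


@pytest.fixture(scope="session")
def tiny_trained():
    """A very small, fast training run for bookkeeping/determinism checks."""
    cfg = PhantomConfig(n_train=1, shape=(10, 32, 32), n_vertebrae=3)
    dataset = build_training_dataset(make_phantom_dataset(3, cfg, 1))
    tc = TrainConfig(epochs=2, batch_size=4, seed=5, augment=None,
                     generator=sf.GeneratorSpec(depth=2, base_channels=4),
                     discriminator=sf.DiscriminatorSpec(n_blocks=2, base_channels=4))
    checkpoint, history = train(dataset, tc)
    return {"dataset": dataset, "config": tc, "checkpoint": checkpoint,
            "history": history}
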