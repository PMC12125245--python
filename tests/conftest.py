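"""Shared fixtures: a small synthetic dataset and a desk-scale model
trained once per session (several tests probe different properties of the
same trained model to keep the suite fast)."""

import numpy as np
import pytest

from stainbridge import (ImagePair, SyntheticConfig, TrainConfig,
                         default_toy_config, generate_dataset,
                         make_schedule, train_model)


@pytest.fixture(scope="session")
def schedule_1000():
    return make_schedule(1000)


@pytest.fixture(scope="session")
def micro_dataset():
    """42 paired 64x64 FOVs at factor 1 (40 train / 2 held out)."""
    cfg = SyntheticConfig(image_size=64, sr_factor=1, nuclei_density=6.0,
                          seed=5)
    pairs, manifest = generate_dataset(cfg, 42, n_holdout=2)
    return pairs, manifest


@pytest.fixture(scope="session")
def micro_model(micro_dataset):
    """Desk-scale denoiser trained on the micro dataset (T = 1000).

    Returns (model, loss_history); training is seeded, so the loss
    trajectory is reproducible.
    """
    pairs, _ = micro_dataset
    train_pairs = [p for p in pairs if p.meta["split"] == "train"]
    losses = []
    model = train_model(
        train_pairs,
        TrainConfig(T=1000, learning_rate=2e-3, batch_size=16,
                    patch_size=32, max_steps=2000, seed=1),
        denoiser_config=default_toy_config(sr_factor=1),
        callback=lambda s, l: losses.append(l))
    return model, np.asarray(losses)


@pytest.fixture(scope="session")
def holdout_pairs(micro_dataset):
    pairs, _ = micro_dataset
    return [p for p in pairs if p.meta["split"] == "holdout"]


@pytest.fixture(scope="session")
def holdout_crop32(holdout_pairs):
    """A 32x32 window of a held-out FOV (cheaper repeated inference)."""
    p = holdout_pairs[0]
    return ImagePair(af=p.af[:, :32, :32], he=p.he[:, :32, :32],
                     factor=p.factor, meta=dict(p.meta))
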