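"""Shared fixtures.

The expensive end-to-end fixtures (a trained tiny detector and its held-out
scenes) are session-scoped so the learning check and the sweep-shape checks
share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import mitecount as mc
from mitecount.train import TrainConfig, train

# problem sizes of the end-to-end checks (kept CPU-friendly)
TRAIN_SCENES = 200
TEST_SCENES = 50
TRAIN_ITERATIONS = 5000


@pytest.fixture(scope="session")
def scene_spec():
    return mc.SceneSpec()


@pytest.fixture(scope="session")
def test_scenes(scene_spec):
    """Held-out scenes, seed-disjoint from every training set used here."""
    return mc.generate_scenes(scene_spec, TEST_SCENES, seed=900_000)


@pytest.fixture(scope="session")
def trained_net(scene_spec):
    """Tiny detector trained end-to-end on synthetic field scenes."""
    scenes = mc.generate_scenes(scene_spec, TRAIN_SCENES, seed=100)
    net = mc.PestNet(k=7, seed=0)
    cfg = TrainConfig(iterations=TRAIN_ITERATIONS, step_size=3500, seed=0,
                      roi_batch=64, roi_fg_cap=16)
    net, _ = train(net, scenes, cfg)
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
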