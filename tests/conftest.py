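"""Shared fixtures.

The heavy artifacts (a trained classifier on the default preset, the full
epsilon sweep, the defense comparison) are session-scoped so the acceptance
tests and the unit tests that need a realistic model share one computation.
"""

import numpy as np
import pytest

import advlesion as al
from advlesion.detection import DetectorConfig, cross_attack_matrix
from advlesion.nn import SmallCNN


@pytest.fixture(scope="session")
def tiny_frozen_cnn():
    """An untrained frozen 16x16 CNN: a cheap but real gradient oracle target."""
    return SmallCNN(image_size=16, channels=(4, 8, 8), seed=7, unsharp_gain=1.0).freeze()


@pytest.fixture(scope="session")
def small_dataset():
    """Small, fast synthetic dataset for unit tests (not the study conditions)."""
    cfg = al.default_config(n_per_class=40, image_size=16, seed=11)
    return al.generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_instance():
    """The study conditions: default preset, n=300/class, 32x32, 2:1 split,
    classifier trained with the default recipe. Seeds follow the global seed 0
    exactly as the experiment orchestration derives them."""
    cfg = al.default_config(n_per_class=300, seed=al.derive_seed(0, "data"))
    dataset = al.generate_dataset(cfg)
    train, val = al.split_train_validation(dataset, (2, 1), seed=al.derive_seed(0, "split"))
    model = al.train_classifier(train, val, al.TrainConfig(seed=al.derive_seed(0, "clf")))
    return {"train": train, "val": val, "model": model}


@pytest.fixture(scope="session")
def sweep_report():
    """Full epsilon sweep on the default preset (the accuracy-vs-eps figure)."""
    return al.run_epsilon_sweep(al.ExperimentConfig(seed=0))


@pytest.fixture(scope="session")
def defense_report():
    """Four-regime defense comparison over three replicate seeds."""
    return al.run_defense_comparison(preset="ct-like", seeds=(0, 1, 2))


@pytest.fixture(scope="session")
def cross_attack_report(default_instance):
    """Detectors trained on BIM at eps=0.032, evaluated against all attacks."""
    grid = {"fgsm": [0.032], "pgd": [0.032], "bim": [0.032]}
    return cross_attack_matrix(al.DETECTOR_KINDS, default_instance["model"],
                               default_instance["train"], default_instance["val"],
                               0.032, grid, DetectorConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
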