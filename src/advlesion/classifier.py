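"""Training and evaluation of the binary malignancy classifier.

The classifier is the fixed attack target: a small CNN trained from scratch
with SGD + momentum on balanced data, with flip/rotation augmentation applied
on the fly during training only. After training the model is frozen —
predictions (and hence attack gradients) are deterministic functions of the
input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .data import LabeledDataset
from .nn import SmallCNN, derive_seed

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "ClassifierModel",
    "preprocess",
    "augment",
    "train_classifier",
    "evaluate_accuracy",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class AugmentConfig:
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    rotation_max_degrees: float = 15.0

    def __post_init__(self):
        for p in (self.hflip_prob, self.vflip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        if self.rotation_max_degrees < 0:
            raise ValueError("rotation_max_degrees must be nonnegative")


@dataclass(frozen=True)
class TrainConfig:
    """SGD recipe. Defaults are desk-scale choices, declared here rather than
    inherited from any published hyperparameter table."""

    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 0.05
    momentum: float = 0.9
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    channels: tuple[int, int, int] = (8, 16, 32)
    #: gain of the fixed unsharp-mask front end (0 disables it); stands in
    #: for the edge-sensitive first stages of a pretrained backbone
    unsharp_gain: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate < 0 or self.momentum < 0:
            raise ValueError("learning_rate and momentum must be nonnegative")


class ClassifierModel:
    """A frozen binary classifier plus its training history.

    Wraps the underlying network and exposes the interface attacks and
    detectors rely on: ``predict_proba`` / ``predict``, ``loss_gradient``,
    and ``features`` (penultimate-layer pooled activations).
    """

    def __init__(self, net: SmallCNN, history: pd.DataFrame | None = None):
        self.net = net
        self.history = history if history is not None else pd.DataFrame(
            columns=["epoch", "loss", "val_accuracy"])

    @property
    def frozen(self) -> bool:
        return self.net.frozen

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict(x)

    def loss_gradient(self, x: np.ndarray, y) -> np.ndarray:
        return self.net.loss_gradient(x, y)

    def features(self, x: np.ndarray) -> np.ndarray:
        return self.net.features(x)

    def block_features(self, x: np.ndarray) -> np.ndarray:
        return self.net.block_features(x)


def preprocess(image: np.ndarray, crop_fraction: float = 1.0, target_size: int | None = None) -> np.ndarray:
    """Center crop, resize, and min-max normalize one image to [0, 1].

    The central ``crop_fraction`` window is extracted, resampled to
    ``target_size`` x ``target_size``, and rescaled so the minimum maps to 0
    and the maximum to 1. A constant image maps to all zeros (the rescale is
    otherwise undefined).
    """
    image = np.asarray(image, dtype=np.float64)
    if not 0.0 < crop_fraction <= 1.0:
        raise ValueError("crop_fraction must lie in (0, 1]")
    h, w = image.shape
    if target_size is None:
        target_size = h
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    ch = max(1, int(round(h * crop_fraction)))
    cw = max(1, int(round(w * crop_fraction)))
    top, left = (h - ch) // 2, (w - cw) // 2
    crop = image[top : top + ch, left : left + cw]
    if crop.shape != (target_size, target_size):
        crop = _sk_resize(crop, (target_size, target_size), order=1,
                          mode="reflect", anti_aliasing=False)
    lo, hi = crop.min(), crop.max()
    if hi - lo == 0:
        return np.zeros_like(crop)
    return (crop - lo) / (hi - lo)


def augment(image: np.ndarray, config: TrainConfig | AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Random flips and rotation with reflect padding; output stays in [0, 1]."""
    aug = config.augmentation if isinstance(config, TrainConfig) else config
    out = np.asarray(image, dtype=np.float64)
    if rng.random() < aug.hflip_prob:
        out = out[:, ::-1]
    if rng.random() < aug.vflip_prob:
        out = out[::-1, :]
    if aug.rotation_max_degrees > 0:
        angle = rng.uniform(-aug.rotation_max_degrees, aug.rotation_max_degrees)
        out = ndimage.rotate(out, angle, reshape=False, mode="reflect", order=1)
    return np.clip(out, 0.0, 1.0)


def _augment_batch(images: np.ndarray, aug: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    return np.stack([augment(img, aug, rng) for img in images])


def _stepped_lr(base: float, epoch: int, total: int) -> float:
    """Step decay: full rate for the first two thirds of training, then /10."""
    return base * (0.1 if epoch > (2 * total) // 3 else 1.0)


def train_classifier(train: LabeledDataset, val: LabeledDataset,
                     config: TrainConfig = TrainConfig()) -> ClassifierModel:
    """Train the CNN with SGD + momentum and on-the-fly augmentation.

    Records per-epoch training loss and validation accuracy, freezes the
    model, and returns it. Deterministic given the config seed.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    net = SmallCNN(image_size=train.image_size, channels=config.channels,
                   unsharp_gain=config.unsharp_gain,
                   seed=derive_seed(config.seed, "init"))
    rng = np.random.default_rng(derive_seed(config.seed, "train"))
    n = len(train)
    history = []
    for epoch in range(1, config.epochs + 1):
        lr = _stepped_lr(config.learning_rate, epoch, config.epochs)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = _augment_batch(train.images[idx], config.augmentation, rng)
            losses.append(net.train_batch(xb, train.labels[idx], lr, config.momentum))
        val_acc = float(np.mean(net.predict(val.images) == val.labels)) if len(val) else np.nan
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_accuracy": val_acc})
    net.freeze()
    return ClassifierModel(net, pd.DataFrame(history))


def evaluate_accuracy(model, dataset: LabeledDataset) -> float:
    """Fraction of argmax predictions equal to labels (ties go to label 0)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if not model.frozen:
        raise ValueError("model must be frozen before evaluation")
    preds = model.predict(dataset.images)
    return float(np.mean(preds == dataset.labels))


# ---------------------------------------------------------------------------
# checkpoints


def _descriptor_hash(descriptor: dict) -> str:
    return hashlib.sha256(json.dumps(descriptor, sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(model: ClassifierModel, path) -> Path:
    """Serialized weights (NPZ) + JSON architecture descriptor with a hash."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.net.state_dict())
    desc = model.net.descriptor()
    desc["hash"] = _descriptor_hash(model.net.descriptor())
    path.with_suffix(".json").write_text(json.dumps(desc, indent=2))
    model.history.to_csv(path.with_suffix(".history.csv"), index=False)
    return path


def load_checkpoint(path) -> ClassifierModel:
    path = Path(path)
    desc = json.loads(path.with_suffix(".json").read_text())
    stored_hash = desc.pop("hash")
    if _descriptor_hash(desc) != stored_hash:
        raise ValueError("checkpoint descriptor hash mismatch (stale or corrupted artifact)")
    net = SmallCNN(image_size=desc["image_size"], channels=tuple(desc["channels"]),
                   n_classes=desc["n_classes"], dtype=np.dtype(desc["dtype"]),
                   in_channels=desc.get("in_channels", 1),
                   input_shift=desc.get("input_shift", 0.5),
                   unsharp_gain=desc.get("unsharp_gain", 0.0))
    with np.load(path) as state:
        net.load_state_dict(dict(state))
    net.freeze()
    hist_path = path.with_suffix(".history.csv")
    history = pd.read_csv(hist_path) if hist_path.exists() else None
    return ClassifierModel(net, history)
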