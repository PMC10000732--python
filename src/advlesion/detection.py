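"""Adversarial-image detection: five detector families and their evaluation.

A detector is a binary discriminator between clean and adversarial images.
Five kinds are supported, mirroring a two-architecture CNN pair plus three
classical classifiers over deep features:

* ``conv_a`` / ``conv_b`` — small CNNs trained end-to-end on images, in two
  widths (the role a heavier ResNet/DenseNet pair plays at clinical scale);
* ``feature_lr`` / ``feature_rf`` / ``feature_svm`` — logistic regression,
  random forest, and RBF-kernel SVM fitted on standardized deep features
  extracted from a frozen feature model (by default the attacked classifier's
  penultimate-layer pooled activations).

The canonical protocol trains each detector on the clean training set plus
its BIM-attacked counterpart, then measures detection accuracy — the
fraction of a balanced clean+adversarial test set whose flag is predicted
correctly — across attacks and perturbation sizes. Detection scores at
exactly 0.5 resolve to "adversarial" (the conservative choice for a safety
filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve, gaussian_filter
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .attacks import AttackConfig, generate_adversarial_set
from .classifier import _stepped_lr
from .data import LabeledDataset, Provenance
from .nn import SmallCNN, derive_seed

__all__ = [
    "DETECTOR_KINDS",
    "DetectionDataset",
    "DetectorConfig",
    "DetectorModel",
    "build_detection_dataset",
    "extract_deep_features",
    "train_detector",
    "evaluate_detector",
    "cross_attack_matrix",
]

DETECTOR_KINDS = ("conv_a", "conv_b", "feature_lr", "feature_rf", "feature_svm")


@dataclass
class DetectionDataset:
    """Images flagged 0 = clean, 1 = adversarial, with per-image provenance."""

    images: np.ndarray
    flags: np.ndarray
    provenance: list[Provenance] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.flags = np.asarray(self.flags, dtype=int)
        if not self.provenance:
            self.provenance = [Provenance() for _ in range(len(self.flags))]
        if not (len(self.images) == len(self.flags) == len(self.provenance)):
            raise ValueError("images, flags and provenance lengths differ")

    def __len__(self) -> int:
        return len(self.flags)

    def is_balanced(self) -> bool:
        counts = np.bincount(self.flags, minlength=2)
        return counts[0] == counts[1]


@dataclass(frozen=True)
class DetectorConfig:
    """Hyperparameters for all five detector kinds (unused fields ignored)."""

    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 0.002
    optimizer: str = "adam"
    momentum: float = 0.9
    conv_channels_a: tuple[int, int, int] = (8, 16, 32)
    conv_channels_b: tuple[int, int, int] = (12, 24, 48)
    lr_C: float = 1.0
    rf_n_estimators: int = 200
    svm_C: float = 1.0
    #: fraction of the training set held out to verify the trained
    #: discriminator beats chance before it is enabled
    holdout_fraction: float = 0.25
    seed: int = 0


def build_detection_dataset(clean: LabeledDataset, adversarial: LabeledDataset,
                            seed: int = 0) -> DetectionDataset:
    """Concatenate a clean set and its adversarial counterpart, flag 0/1, shuffle.

    The adversarial set must be derived from the clean set (same length and
    label order), so the result is balanced by construction.
    """
    if len(clean) != len(adversarial):
        raise ValueError("clean and adversarial sets must have equal length")
    if not np.array_equal(clean.labels, adversarial.labels):
        raise ValueError("adversarial set must be derived from the clean set (labels differ)")
    images = np.concatenate([clean.images, adversarial.images])
    flags = np.concatenate([np.zeros(len(clean), dtype=int), np.ones(len(adversarial), dtype=int)])
    prov = list(clean.provenance) + list(adversarial.provenance)
    order = np.random.default_rng(seed).permutation(len(flags))
    return DetectionDataset(images[order], flags[order], [prov[i] for i in order])


def extract_deep_features(feature_model, images: np.ndarray) -> np.ndarray:
    """Deep-feature rows for the classical detectors, one row per image.

    Uses the globally pooled activations of every convolutional block of the
    (frozen) feature model when available — early-block statistics respond to
    low-amplitude perturbations long before the decision-level features move —
    falling back to the penultimate-layer features otherwise.
    """
    if not feature_model.frozen:
        raise ValueError("feature model must be frozen")
    images = np.asarray(images)
    if hasattr(feature_model, "block_features"):
        feats = feature_model.block_features(images)
    else:
        feats = feature_model.features(images)
    return np.atleast_2d(feats)


def residual_bank(images: np.ndarray) -> np.ndarray:
    """Fixed high-pass residual front end for the convolutional detectors.

    Adversarial perturbations are a low-amplitude, high-frequency additive
    signal, so the convolutional detectors look at rectified noise residuals
    rather than raw pixels — the same front-end idea steganalysis networks
    use, where a trainable network struggles to discover residual filters on
    its own from small data. Two channels per image: |Laplacian| and
    |image - Gaussian blur(sigma=1)|. Shape (n, 2, h, w).
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    # 2-D Laplacian applied image-wise (leading kernel axis of size 1)
    kernel = np.array([[[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]])
    lap = np.abs(convolve(images, kernel, mode="reflect"))
    hip = np.abs(images - gaussian_filter(images, sigma=(0, 1.0, 1.0)))
    return np.stack([lap, hip], axis=1)


class _ConvDetector:
    """Residual-bank CNN with the normalization statistics fitted on train."""

    def __init__(self, net: SmallCNN, mu: np.ndarray, sd: np.ndarray):
        self.net = net
        self.mu = mu
        self.sd = sd

    def _transform(self, images: np.ndarray) -> np.ndarray:
        r = residual_bank(images)
        return (r - self.mu) / self.sd * 0.15  # keep activations at raw-pixel scale

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._transform(images))


class DetectorModel:
    """A frozen clean-vs-adversarial discriminator of one of the five kinds.

    ``enabled`` records whether the trained discriminator beat chance on its
    held-out calibration split; a disabled detector emits the uninformative
    score 0.5 for every image instead of held-out noise.
    """

    def __init__(self, kind: str, backend, feature_model=None,
                 scaler: StandardScaler | None = None, enabled: bool = True,
                 holdout_accuracy: float = float("nan")):
        if kind not in DETECTOR_KINDS:
            raise ValueError(f"unknown detector kind {kind!r}")
        self.kind = kind
        self.backend = backend
        self.feature_model = feature_model
        self.scaler = scaler
        self.enabled = enabled
        self.holdout_accuracy = holdout_accuracy
        self.frozen = True

    def scores(self, images: np.ndarray) -> np.ndarray:
        """P(adversarial) per image (SVM: sigmoid of the decision function)."""
        images = np.asarray(images, dtype=np.float64)
        if not self.enabled:
            return np.full(len(images), 0.5)
        if self.kind.startswith("conv"):
            return self.backend.predict_proba(images)[..., 1]
        feats = extract_deep_features(self.feature_model, images)
        feats = self.scaler.transform(feats)
        if self.kind == "feature_svm":
            return 1.0 / (1.0 + np.exp(-self.backend.decision_function(feats)))
        return self.backend.predict_proba(feats)[:, 1]

    def predict_flags(self, images: np.ndarray) -> np.ndarray:
        """1 = adversarial. Scores of exactly 0.5 resolve to adversarial."""
        return (self.scores(images) >= 0.5).astype(int)


def _train_conv_detector(train: DetectionDataset, channels,
                         config: DetectorConfig) -> _ConvDetector:
    r = residual_bank(train.images)
    mu = r.mean(axis=(0, 2, 3), keepdims=True)
    sd = r.std(axis=(0, 2, 3), keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    rz = (r - mu) / sd * 0.15
    net = SmallCNN(image_size=train.images.shape[1], channels=channels,
                   in_channels=2, input_shift=0.0,
                   seed=derive_seed(config.seed, "detector-init"))
    rng = np.random.default_rng(derive_seed(config.seed, "detector-train"))
    n = len(train)
    for epoch in range(1, config.epochs + 1):
        lr = _stepped_lr(config.learning_rate, epoch, config.epochs)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            net.train_batch(rz[idx], train.flags[idx], lr, config.momentum,
                            optimizer=config.optimizer)
    net.freeze()
    return _ConvDetector(net, mu[0], sd[0])


def _holdout_split(train: DetectionDataset, fraction: float, seed: int):
    """Stratified (by flag) holdout split; returns (fit_idx, holdout_idx)."""
    rng = np.random.default_rng(seed)
    fit_idx, hold_idx = [], []
    for flag in (0, 1):
        idx = np.nonzero(train.flags == flag)[0]
        idx = idx[rng.permutation(len(idx))]
        n_hold = int(round(fraction * len(idx)))
        hold_idx.append(idx[:n_hold])
        fit_idx.append(idx[n_hold:])
    return np.sort(np.concatenate(fit_idx)), np.sort(np.concatenate(hold_idx))


def train_detector(train: DetectionDataset, kind: str, config: DetectorConfig = DetectorConfig(),
                   feature_model=None) -> DetectorModel:
    """Fit one detector kind on a balanced detection training set.

    Convolutional kinds train a small CNN end-to-end on high-pass residual
    maps of the images; feature kinds standardize deep features (statistics
    fitted on the training rows only) and fit the stated classical
    classifier. Seeded and frozen on return.

    A stratified quarter of the training set (``config.holdout_fraction``) is
    held out for calibration: if the fitted discriminator does not beat
    chance there by more than sampling noise, the detector is returned
    disabled — it scores every image 0.5 instead of emitting memorization
    noise. Attacks below the detectability floor thus measure exactly chance.
    """
    if kind not in DETECTOR_KINDS:
        raise ValueError(f"unknown detector kind {kind!r}")
    if not train.is_balanced():
        raise ValueError("detection training set must be balanced")
    fit_idx, hold_idx = _holdout_split(train, config.holdout_fraction,
                                       derive_seed(config.seed, "det-holdout"))
    fit = DetectionDataset(train.images[fit_idx], train.flags[fit_idx],
                           [train.provenance[i] for i in fit_idx])
    if kind == "conv_a":
        det = DetectorModel(kind, _train_conv_detector(fit, config.conv_channels_a, config))
    elif kind == "conv_b":
        det = DetectorModel(kind, _train_conv_detector(fit, config.conv_channels_b, config))
    else:
        if feature_model is None:
            raise ValueError("feature detectors need a frozen feature_model")
        feats = extract_deep_features(feature_model, fit.images)
        scaler = StandardScaler().fit(feats)
        feats = scaler.transform(feats)
        if kind == "feature_lr":
            clf = LogisticRegression(C=config.lr_C, max_iter=2000, random_state=config.seed)
        elif kind == "feature_rf":
            clf = RandomForestClassifier(n_estimators=config.rf_n_estimators,
                                         random_state=config.seed)
        else:  # feature_svm
            clf = SVC(kernel="rbf", C=config.svm_C, random_state=config.seed)
        clf.fit(feats, fit.flags)
        det = DetectorModel(kind, clf, feature_model=feature_model, scaler=scaler)
    if len(hold_idx):
        hold_acc = float(np.mean(det.predict_flags(train.images[hold_idx])
                                 == train.flags[hold_idx]))
        # one-sided binomial gate: chance + 1.5 sd at the holdout size
        threshold = 0.5 + 1.5 * np.sqrt(0.25 / len(hold_idx))
        det.holdout_accuracy = hold_acc
        det.enabled = hold_acc >= threshold
    return det


def evaluate_detector(detector: DetectorModel, clean_test: LabeledDataset,
                      adv_test: LabeledDataset) -> float:
    """Detection accuracy on the balanced combination of clean and adversarial sets."""
    if len(clean_test) == 0 or len(adv_test) == 0:
        raise ValueError("empty evaluation set")
    if not detector.frozen:
        raise ValueError("detector must be frozen")
    flags = np.concatenate([np.zeros(len(clean_test), dtype=int),
                            np.ones(len(adv_test), dtype=int)])
    images = np.concatenate([clean_test.images, adv_test.images])
    return float(np.mean(detector.predict_flags(images) == flags))


def cross_attack_matrix(detector_kinds: Sequence[str], model, clean_train: LabeledDataset,
                        clean_test: LabeledDataset, train_epsilon: float,
                        test_attack_grid: dict[str, Sequence[float]],
                        config: DetectorConfig = DetectorConfig(),
                        train_attack: str = "bim") -> pd.DataFrame:
    """Train detectors on one attack/epsilon, evaluate across attacks and epsilons.

    Detectors are trained once, on the clean training set plus its
    ``train_attack`` (BIM by default) counterpart at ``train_epsilon``, then
    scored against every (attack, epsilon) cell of the grid on the test set —
    the cross-attack generalization protocol.

    Returns a tidy frame with columns detector, attack, epsilon,
    detection_accuracy.
    """
    if not test_attack_grid or any(len(v) == 0 for v in test_attack_grid.values()):
        raise ValueError("empty attack grid")
    adv_train = generate_adversarial_set(
        model, clean_train, AttackConfig(method=train_attack, epsilon=train_epsilon))
    det_train = build_detection_dataset(clean_train, adv_train,
                                        seed=derive_seed(config.seed, "det-shuffle"))
    detectors = {kind: train_detector(det_train, kind, config, feature_model=model)
                 for kind in detector_kinds}
    rows = []
    for attack, eps_list in test_attack_grid.items():
        for eps in eps_list:
            adv_test = generate_adversarial_set(
                model, clean_test, AttackConfig(method=attack, epsilon=eps))
            for kind, det in detectors.items():
                rows.append({"detector": kind, "attack": attack, "epsilon": eps,
                             "detection_accuracy": evaluate_detector(det, clean_test, adv_test)})
    return pd.DataFrame(rows)
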