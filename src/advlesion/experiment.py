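"""End-to-end experiment orchestration: the epsilon sweep and report I/O.

``run_epsilon_sweep`` reproduces the canonical sensitivity protocol: train
the classifier once, then for each perturbation budget on the grid generate
adversarial versions of the train and test sets, train all detectors on the
BIM training adversarials at that budget (matched-epsilon condition), and
record (a) classifier accuracy on each attack's adversarial test set and
(b) each detector's detection accuracy on the combined clean+adversarial
test set. As epsilon grows, classifier accuracy falls while detection
accuracy rises.

A single global seed deterministically derives per-stage seeds (hash of
seed + stage name), so stages are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .attacks import AttackConfig, generate_adversarial_set
from .classifier import TrainConfig, evaluate_accuracy, train_classifier
from .data import default_config, generate_dataset, split_train_validation
from .detection import (DETECTOR_KINDS, DetectorConfig, build_detection_dataset,
                        evaluate_detector, train_detector)
from .nn import derive_seed

__all__ = [
    "DEFAULT_EPSILON_GRID",
    "ExperimentConfig",
    "SweepReport",
    "run_epsilon_sweep",
    "write_report",
    "read_report",
]

#: Doubling ladder bracketing the canonical 0.004 and 0.008 budgets.
DEFAULT_EPSILON_GRID = (0.001, 0.002, 0.004, 0.008, 0.016, 0.032)

SCHEMA_VERSION = "sweep-v1"


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one sweep run."""

    preset: str = "ct-like"
    n_per_class: int = 300
    attacks: tuple[str, ...] = ("fgsm", "pgd", "bim")
    epsilon_grid: tuple[float, ...] = DEFAULT_EPSILON_GRID
    detector_kinds: tuple[str, ...] = DETECTOR_KINDS
    train_config: TrainConfig = field(default_factory=TrainConfig)
    detector_config: DetectorConfig = field(default_factory=DetectorConfig)
    seed: int = 0

    def __post_init__(self):
        eps = list(self.epsilon_grid)
        if any(e < 0 for e in eps) or eps != sorted(set(eps)):
            raise ValueError("epsilon_grid must be strictly increasing and nonnegative")
        unknown = set(self.detector_kinds) - set(DETECTOR_KINDS)
        if unknown:
            raise ValueError(f"unknown detector kinds: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "train_config" in raw:
            raw["train_config"] = TrainConfig(**raw["train_config"])
        if "detector_config" in raw:
            raw["detector_config"] = DetectorConfig(**raw["detector_config"])
        for key in ("attacks", "epsilon_grid", "detector_kinds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SweepReport:
    """Tables behind the accuracy-vs-epsilon figure.

    ``classifier`` columns: attack, epsilon, adversarial_accuracy.
    ``detection`` columns: detector, attack, epsilon, detection_accuracy.
    """

    classifier: pd.DataFrame
    detection: pd.DataFrame
    clean_accuracy: float
    config: ExperimentConfig | None = None


def run_epsilon_sweep(config: ExperimentConfig = ExperimentConfig(),
                      model=None, train=None, val=None) -> SweepReport:
    """Run the full attack/detection sweep; see the module docstring.

    A pre-trained frozen model plus its train/val split may be passed in to
    skip retraining (all three must then be given together).
    """
    if model is None:
        data_cfg = default_config(config.preset, n_per_class=config.n_per_class,
                                  seed=derive_seed(config.seed, "data"))
        dataset = generate_dataset(data_cfg)
        train, val = split_train_validation(dataset, (2, 1),
                                            seed=derive_seed(config.seed, "split"))
        tc = TrainConfig(**{**config.train_config.__dict__,
                            "seed": derive_seed(config.seed, "clf")})
        model = train_classifier(train, val, tc)
    clean_acc = evaluate_accuracy(model, val)
    clf_rows, det_rows = [], []
    for eps in config.epsilon_grid:
        bim_cfg = AttackConfig(method="bim", epsilon=eps)
        adv_train = generate_adversarial_set(model, train, bim_cfg)
        det_train = build_detection_dataset(
            train, adv_train, seed=derive_seed(config.seed, f"shuffle-{eps}"))
        dc = DetectorConfig(**{**config.detector_config.__dict__,
                               "seed": derive_seed(config.seed, f"det-{eps}")})
        detectors = {kind: train_detector(det_train, kind, dc, feature_model=model)
                     for kind in config.detector_kinds}
        for attack in config.attacks:
            adv_val = generate_adversarial_set(
                model, val, AttackConfig(method=attack, epsilon=eps))
            clf_rows.append({"attack": attack, "epsilon": eps,
                             "adversarial_accuracy": evaluate_accuracy(model, adv_val)})
            for kind, det in detectors.items():
                det_rows.append({"detector": kind, "attack": attack, "epsilon": eps,
                                 "detection_accuracy": evaluate_detector(det, val, adv_val)})
    return SweepReport(pd.DataFrame(clf_rows), pd.DataFrame(det_rows), clean_acc, config)


def write_report(report: SweepReport, path) -> list[Path]:
    """Emit a sweep report as versioned CSVs plus a JSON twin; returns the paths.

    ``path`` is a stem: ``<stem>.classifier.csv``, ``<stem>.detection.csv``
    and ``<stem>.json`` are written. The CSV and JSON carry identical values
    and round-trip through :func:`read_report`.
    """
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    clf_path = stem.with_suffix(".classifier.csv")
    det_path = stem.with_suffix(".detection.csv")
    json_path = stem.with_suffix(".json")
    clf = report.classifier.copy()
    det = report.detection.copy()
    clf.insert(0, "schema", SCHEMA_VERSION)
    det.insert(0, "schema", SCHEMA_VERSION)
    clf.to_csv(clf_path, index=False)
    det.to_csv(det_path, index=False)
    json_path.write_text(json.dumps({
        "schema": SCHEMA_VERSION,
        "clean_accuracy": report.clean_accuracy,
        "classifier": report.classifier.to_dict(orient="records"),
        "detection": report.detection.to_dict(orient="records"),
    }, indent=2))
    return [clf_path, det_path, json_path]


def read_report(path) -> SweepReport:
    stem = Path(path)
    payload = json.loads(stem.with_suffix(".json").read_text())
    if payload.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema {payload.get('schema')!r}")
    clf = pd.read_csv(stem.with_suffix(".classifier.csv"))
    det = pd.read_csv(stem.with_suffix(".detection.csv"))
    if (clf["schema"] != SCHEMA_VERSION).any() or (det["schema"] != SCHEMA_VERSION).any():
        raise ValueError("CSV schema version mismatch")
    return SweepReport(clf.drop(columns="schema"), det.drop(columns="schema"),
                       float(payload["clean_accuracy"]))
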