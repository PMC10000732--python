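"""Detection: dataset construction, deep features, the five detector kinds."""

import numpy as np
import pytest

import advlesion as al
from advlesion.data import LabeledDataset, Provenance
from advlesion.detection import (DETECTOR_KINDS, DetectionDataset, DetectorConfig,
                                 DetectorModel, _holdout_split, build_detection_dataset,
                                 cross_attack_matrix, evaluate_detector,
                                 extract_deep_features, train_detector)
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler


class _StubFeatureModel:
    """Feature model whose deep features are the flattened image pixels."""
    frozen = True

    def block_features(self, images):
        images = np.atleast_3d(np.asarray(images))
        return images.reshape(len(images), -1)


def _gaussian_detection_problem(rng, n=300, d=16, shift=3.0):
    """Clean features ~ N(0, I), adversarial ~ N(shift, I), as 4x4 'images'."""
    side = int(np.sqrt(d))
    clean = rng.normal(0.0, 1.0, (n, side, side))
    adv = rng.normal(shift, 1.0, (n, side, side))
    flags = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    images = np.concatenate([clean, adv])
    order = rng.permutation(2 * n)
    return DetectionDataset(images[order], flags[order])


class TestBuildDetectionDataset:
    def test_concatenation_and_balance(self, small_dataset, tiny_frozen_cnn):
        adv = al.generate_adversarial_set(
            tiny_frozen_cnn, small_dataset, al.AttackConfig(method="bim", epsilon=0.02, steps=3))
        det = build_detection_dataset(small_dataset, adv, seed=0)
        assert len(det) == 2 * len(small_dataset)
        assert det.is_balanced()

    def test_provenance_tracks_flags(self, small_dataset, tiny_frozen_cnn):
        adv = al.generate_adversarial_set(
            tiny_frozen_cnn, small_dataset, al.AttackConfig(method="pgd", epsilon=0.02, steps=2))
        det = build_detection_dataset(small_dataset, adv, seed=3)
        for flag, prov in zip(det.flags, det.provenance):
            assert (prov.source == "adversarial") == bool(flag)

    def test_same_seed_same_shuffle(self, small_dataset, tiny_frozen_cnn):
        adv = al.generate_adversarial_set(
            tiny_frozen_cnn, small_dataset, al.AttackConfig(method="bim", epsilon=0.02, steps=2))
        a = build_detection_dataset(small_dataset, adv, seed=7)
        b = build_detection_dataset(small_dataset, adv, seed=7)
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.flags, b.flags)

    def test_length_mismatch_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            build_detection_dataset(small_dataset, small_dataset.subset(np.arange(5)))


class TestDeepFeatures:
    def test_deterministic_rows_and_shape(self, tiny_frozen_cnn, rng):
        imgs = rng.random((4, 16, 16))
        doubled = np.concatenate([imgs, imgs])
        feats = extract_deep_features(tiny_frozen_cnn, doubled)
        assert feats.shape == (8, sum(tiny_frozen_cnn.channels))
        np.testing.assert_array_equal(feats[:4], feats[4:])

    def test_unfrozen_feature_model_rejected(self, rng):
        from advlesion.nn import SmallCNN
        with pytest.raises(ValueError):
            extract_deep_features(SmallCNN(image_size=16, channels=(4, 4, 4)),
                                  rng.random((2, 16, 16)))

    def test_features_linearly_separate_strong_attacks(self, default_instance):
        """Clean vs large-eps adversarial deep features admit a linear probe
        with high training accuracy (the feature clouds barely overlap)."""
        model, train = default_instance["model"], default_instance["train"]
        adv = al.generate_adversarial_set(
            model, train, al.AttackConfig(method="bim", epsilon=0.048))
        X = np.concatenate([extract_deep_features(model, train.images),
                            extract_deep_features(model, adv.images)])
        y = np.concatenate([np.zeros(len(train)), np.ones(len(adv))])
        probe = make_pipeline(StandardScaler(), LogisticRegression(max_iter=5000)).fit(X, y)
        assert probe.score(X, y) >= 0.95


class TestTrainDetector:
    def test_gaussian_shift_problem_solved(self, rng):
        det_train = _gaussian_detection_problem(rng)
        det = train_detector(det_train, "feature_lr", DetectorConfig(seed=0),
                             feature_model=_StubFeatureModel())
        probe = _gaussian_detection_problem(rng, n=200)
        acc = np.mean(det.predict_flags(probe.images) == probe.flags)
        assert acc >= 0.99

    def test_seeded_determinism(self, rng):
        det_train = _gaussian_detection_problem(rng)
        probe = _gaussian_detection_problem(rng, n=100)
        preds = []
        for _ in range(2):
            det = train_detector(det_train, "feature_rf", DetectorConfig(seed=5),
                                 feature_model=_StubFeatureModel())
            preds.append(det.predict_flags(probe.images))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_flag_inversion_symmetry(self, rng):
        det_train = _gaussian_detection_problem(rng, shift=1.0)
        inverted = DetectionDataset(det_train.images, 1 - det_train.flags)
        probe = _gaussian_detection_problem(rng, n=200, shift=1.0)
        acc, inv_acc = [], []
        for data, out in ((det_train, acc), (inverted, inv_acc)):
            det = train_detector(data, "feature_lr", DetectorConfig(seed=0),
                                 feature_model=_StubFeatureModel())
            out.append(np.mean(det.predict_flags(probe.images) == probe.flags))
        assert acc[0] + inv_acc[0] == pytest.approx(1.0, abs=0.05)

    def test_uninformative_detector_disabled(self, rng):
        """Pure-noise flags: the calibration gate must disable the detector,
        which then scores exactly chance on any balanced set."""
        noise = DetectionDataset(rng.normal(0, 1, (400, 8, 8)),
                                 np.repeat([0, 1], 200))
        det = train_detector(noise, "feature_lr", DetectorConfig(seed=0),
                             feature_model=_StubFeatureModel())
        assert not det.enabled
        assert (det.scores(rng.normal(0, 1, (10, 8, 8))) == 0.5).all()

    def test_unknown_kind_and_unbalanced_rejected(self, rng):
        det_train = _gaussian_detection_problem(rng, n=50)
        with pytest.raises(ValueError):
            train_detector(det_train, "conv_z")
        unbalanced = DetectionDataset(det_train.images[:30], det_train.flags[:30] * 0)
        with pytest.raises(ValueError):
            train_detector(unbalanced, "feature_lr", feature_model=_StubFeatureModel())

    def test_feature_kind_requires_feature_model(self, rng):
        with pytest.raises(ValueError):
            train_detector(_gaussian_detection_problem(rng, n=50), "feature_svm")

    def test_standardization_fitted_on_fit_rows_only(self, rng):
        """Leakage guard: scaler statistics come from the post-holdout fit rows."""
        cfg = DetectorConfig(seed=0)
        det_train = _gaussian_detection_problem(rng)
        det = train_detector(det_train, "feature_lr", cfg,
                             feature_model=_StubFeatureModel())
        fit_idx, _ = _holdout_split(det_train, cfg.holdout_fraction,
                                    al.derive_seed(cfg.seed, "det-holdout"))
        expected = extract_deep_features(_StubFeatureModel(),
                                         det_train.images[fit_idx]).mean(axis=0)
        np.testing.assert_allclose(det.scaler.mean_, expected, atol=1e-12)


class TestEvaluateDetector:
    def _sets(self, rng, n=40):
        imgs = rng.random((n, 8, 8))
        labels = rng.integers(0, 2, n)
        return (LabeledDataset(imgs, labels),
                LabeledDataset(rng.random((n, 8, 8)), labels,
                               [Provenance("adversarial", "bim", 0.01)] * n))

    def test_constant_detectors_score_half(self, rng):
        clean, adv = self._sets(rng)
        class Stub:
            frozen = True
            def __init__(self, flag): self.flag = flag
            def predict_flags(self, images): return np.full(len(images), self.flag, int)
        assert evaluate_detector(Stub(0), clean, adv) == 0.5
        assert evaluate_detector(Stub(1), clean, adv) == 0.5

    def test_perfect_detector_scores_one(self, rng):
        clean, adv = self._sets(rng)
        class Oracle:
            frozen = True
            def __init__(self, adv_keys): self.keys = adv_keys
            def predict_flags(self, images):
                return np.array([img.tobytes() in self.keys for img in images], int)
        oracle = Oracle({img.tobytes() for img in adv.images})
        assert evaluate_detector(oracle, clean, adv) == 1.0

    def test_empty_sets_rejected(self, rng):
        clean, adv = self._sets(rng)
        empty = clean.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            evaluate_detector(DetectorModel("feature_lr", None, enabled=False), empty, adv)


class TestCrossAttackMatrix:
    def test_grid_shape_and_range(self, cross_attack_report):
        assert len(cross_attack_report) == len(DETECTOR_KINDS) * 3
        assert cross_attack_report.detection_accuracy.between(0, 1).all()
        assert set(cross_attack_report.attack) == {"fgsm", "pgd", "bim"}

    def test_empty_grid_rejected(self, tiny_frozen_cnn, small_dataset):
        with pytest.raises(ValueError):
            cross_attack_matrix(["feature_lr"], tiny_frozen_cnn, small_dataset,
                                small_dataset, 0.01, {})
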