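"""Defense evaluation: the adjusted-accuracy formula and adversarial training."""

import numpy as np
import pytest

import advlesion as al
from advlesion.data import LabeledDataset, Provenance
from advlesion.defense import (DefenseConfig, adversarial_train,
                               baseline_combined_accuracy, detection_filtered_accuracy)


class _TableModel:
    """Classifier stub: the prediction for each image is a lookup table."""
    frozen = True

    def __init__(self, lookup=None):
        self._lookup = lookup or {}

    def predict(self, images):
        return np.array([self._lookup[img.tobytes()] for img in images])


class _TableDetector:
    frozen = True

    def __init__(self, flagged_keys):
        self.flagged = flagged_keys

    def predict_flags(self, images):
        return np.array([img.tobytes() in self.flagged for img in images], int)


def _make_case(rng, n_clean, n_adv, clean_correct, adv_correct,
               flagged_clean, flagged_adv):
    """Build datasets plus model/detector stubs realizing exact count tables."""
    imgs = rng.random((n_clean + n_adv, 4, 4))
    labels = rng.integers(0, 2, n_clean + n_adv)
    clean = LabeledDataset(imgs[:n_clean], labels[:n_clean])
    adv = LabeledDataset(imgs[n_clean:], labels[n_clean:],
                         [Provenance("adversarial", "bim", 0.01)] * n_adv)
    model = _TableModel()
    lookup = {}
    for i, (img, lab) in enumerate(zip(clean.images, clean.labels)):
        lookup[img.tobytes()] = lab if i < clean_correct else 1 - lab
    for i, (img, lab) in enumerate(zip(adv.images, adv.labels)):
        lookup[img.tobytes()] = lab if i < adv_correct else 1 - lab
    model._lookup = lookup
    flagged = ({img.tobytes() for img in clean.images[n_clean - flagged_clean:]}
               | {img.tobytes() for img in adv.images[:flagged_adv]})
    return clean, adv, model, _TableDetector(flagged)


def _enumerate_adjusted(clean, adv, model, detector):
    """Brute-force item-level oracle for the adjusted accuracy."""
    numer = denom = 0
    for ds, is_adv in ((clean, False), (adv, True)):
        for img, lab in zip(ds.images, ds.labels):
            flagged = bool(detector.predict_flags(img[None])[0])
            if flagged and is_adv:
                continue  # correctly excluded: drops out entirely
            if flagged and not is_adv:
                denom += 1  # wrongly excluded clean counts as an error
                continue
            denom += 1
            numer += int(model.predict(img[None])[0] == lab)
    return numer / denom if denom else 0.0


class TestCombinedBaseline:
    def test_balanced_mixture_identity(self, rng):
        clean, adv, model, _ = _make_case(rng, 50, 50, 40, 10, 0, 0)
        combined = baseline_combined_accuracy(model, clean, adv)
        assert combined == pytest.approx((40 / 50 + 10 / 50) / 2)

    def test_perfect_clean_zero_adv_scores_half(self, rng):
        clean, adv, model, _ = _make_case(rng, 30, 30, 30, 0, 0, 0)
        assert baseline_combined_accuracy(model, clean, adv) == 0.5

    def test_size_mismatch_rejected(self, rng):
        clean, adv, model, _ = _make_case(rng, 20, 20, 10, 5, 0, 0)
        with pytest.raises(ValueError):
            baseline_combined_accuracy(model, clean, adv.subset(np.arange(10)))


class TestAdjustedAccuracy:
    def test_null_detector_equals_combined_baseline(self, rng):
        clean, adv, model, detector = _make_case(rng, 60, 60, 45, 12, 0, 0)
        acc, counts = detection_filtered_accuracy(model, detector, clean, adv)
        assert acc == pytest.approx(baseline_combined_accuracy(model, clean, adv))
        assert counts == {"retained": 120, "excluded_clean": 0, "excluded_adv": 0}

    def test_perfect_detector_equals_clean_accuracy(self, rng):
        clean, adv, model, detector = _make_case(rng, 60, 60, 45, 12, 0, 60)
        acc, counts = detection_filtered_accuracy(model, detector, clean, adv)
        assert acc == pytest.approx(45 / 60)
        assert counts == {"retained": 60, "excluded_clean": 0, "excluded_adv": 60}

    def test_hand_worked_example(self, rng):
        """100 clean + 100 adversarial; 90 adversarial and 5 clean flagged;
        model correct on 76 of 95 retained clean and 1 of 10 retained
        adversarial -> 77 / (105 + 5) = 0.700."""
        clean, adv, model, detector = _make_case(
            rng, 100, 100, clean_correct=76, adv_correct=91,
            flagged_clean=5, flagged_adv=90)
        # adv_correct=91: the 90 flagged are the first 90; the single correct
        # retained adversarial must be among the last 10 -> rebuild lookup
        for i, (img, lab) in enumerate(zip(adv.images, adv.labels)):
            model._lookup[img.tobytes()] = lab if i == 95 else 1 - lab
        acc, counts = detection_filtered_accuracy(model, detector, clean, adv)
        assert counts == {"retained": 105, "excluded_clean": 5, "excluded_adv": 90}
        assert acc == pytest.approx(77 / 110)
        assert acc == pytest.approx(0.700)

    def test_everything_flagged_scores_zero(self, rng):
        """Flagging every image leaves no retained correct answers, and the
        wrongly excluded clean half keeps the denominator positive: 0/n."""
        clean, adv, model, detector = _make_case(rng, 10, 10, 5, 5, 10, 10)
        acc, counts = detection_filtered_accuracy(model, detector, clean, adv)
        assert acc == 0.0
        assert counts == {"retained": 0, "excluded_clean": 10, "excluded_adv": 10}


    def test_formula_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            clean, adv, model, detector = _make_case(
                rng, n, n,
                clean_correct=int(rng.integers(0, n + 1)),
                adv_correct=int(rng.integers(0, n + 1)),
                flagged_clean=int(rng.integers(0, n)),
                flagged_adv=int(rng.integers(0, n)))
            acc, _ = detection_filtered_accuracy(model, detector, clean, adv)
            assert acc == pytest.approx(_enumerate_adjusted(clean, adv, model, detector))

    def test_monotone_under_detector_improvement(self, rng):
        """Catching more misclassified adversarials (no new false positives)
        never decreases the adjusted accuracy; checked against the item-level
        oracle on 100 randomized tables."""
        for _ in range(100):
            n = int(rng.integers(10, 40))
            adv_correct = 0  # regime where the attack fully succeeds
            clean_correct = int(rng.integers(0, n + 1))
            flagged_clean = int(rng.integers(0, n // 2))
            flagged_adv = int(rng.integers(0, n))
            clean, adv, model, det_weak = _make_case(
                rng, n, n, clean_correct, adv_correct, flagged_clean, flagged_adv)
            extra = int(rng.integers(flagged_adv, n + 1))
            det_strong = type(det_weak)(
                ({img.tobytes() for img in clean.images[n - flagged_clean:]}
                 | {img.tobytes() for img in adv.images[:extra]}))
            weak, _ = detection_filtered_accuracy(model, det_weak, clean, adv)
            strong, _ = detection_filtered_accuracy(model, det_strong, clean, adv)
            assert strong >= weak - 1e-12
            assert strong == pytest.approx(
                _enumerate_adjusted(clean, adv, model, det_strong))


class TestAdversarialTraining:
    def test_zero_fraction_reduces_to_ordinary_training(self, small_dataset):
        train, val = al.split_train_validation(small_dataset, (2, 1), seed=0)
        tc = al.TrainConfig(epochs=4, seed=0)
        plain = al.train_classifier(train, val, tc)
        degenerate = adversarial_train(
            train, val, tc, DefenseConfig(adv_fraction_per_batch=0.0))
        np.testing.assert_array_equal(plain.predict_proba(val.images),
                                      degenerate.predict_proba(val.images))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            DefenseConfig(adv_fraction_per_batch=1.5)

    def test_empty_training_set_rejected(self, small_dataset):
        empty = small_dataset.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            adversarial_train(empty, small_dataset)


class TestDefenseReport:
    def test_four_regimes_in_range_and_baseline_lowest(self, defense_report):
        acc = defense_report.accuracies.set_index("regime")["accuracy_mean"]
        assert set(acc.index) == {"baseline", "detection", "training", "combined"}
        assert acc.between(0, 1).all()
        assert acc["baseline"] == acc.min()

    def test_counts_consistent_with_test_set_size(self, defense_report):
        counts = defense_report.counts.set_index("regime")
        total = counts.loc["detection"].sum()
        assert total == counts.loc["baseline", "retained"]

    def test_robustness_transferred_to_adversarial_set(self, defense_report):
        """The adversarially trained model beats the undefended one on the
        adversarial half by a wide margin, at bounded clean cost."""
        diag = defense_report.diagnostics
        assert (diag.adv_robust - diag.adv_base).mean() >= 0.20
        assert (diag.clean_base - diag.clean_robust).mean() <= 0.15
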