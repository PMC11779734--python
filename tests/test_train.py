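"""Metrics, loss, augmentation, and training-protocol contracts."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfma.io_datasets import ImageSample
from dfma.nn import Tensor
from dfma.train import (AugmentConfig, ConfusionMatrix, EarlyStopper,
                        TrainConfig, augment, confusion, early_stop_epoch,
                        miou, precision_recall_accuracy, segmentation_loss)

from conftest import numeric_gradient


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self, rng):
        truth = rng.integers(0, 4, size=(16, 16))
        cm = confusion(truth, truth, 4)
        assert (cm.counts - np.diag(np.diag(cm.counts)) == 0).all()

    def test_hand_enumerated_example(self):
        cm = confusion(np.array([0, 1, 1, 1]), np.array([0, 0, 1, 1]), 2)
        assert cm.counts[0, 0] == 1
        assert cm.counts[0, 1] == 1
        assert cm.counts[1, 1] == 2

    def test_additive_over_batches(self, rng):
        t1, p1 = rng.integers(0, 4, (2, 8, 8))
        t2, p2 = rng.integers(0, 4, (2, 8, 8))
        total = confusion(np.concatenate([p1, p2]), np.concatenate([t1, t2]), 4)
        summed = confusion(p1, t1, 4) + confusion(p2, t2, 4)
        np.testing.assert_array_equal(total.counts, summed.counts)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([0, 5]), np.array([0, 1]), 4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros(3, dtype=int), np.zeros(4, dtype=int), 4)


class TestMiou:
    def test_perfect_is_one(self, rng):
        truth = rng.integers(0, 4, size=(16, 16))
        assert miou(confusion(truth, truth, 4)) == 1.0

    def test_hand_example_seven_twelfths(self):
        cm = confusion(np.array([0, 1, 1, 1]), np.array([0, 0, 1, 1]), 2)
        assert miou(cm) == pytest.approx(7 / 12)

    def test_constant_background_prediction_structure(self):
        truth = np.array([0, 0, 1, 2, 3])
        cm = confusion(np.zeros(5, dtype=int), truth, 4)
        ious = [cm.one_vs_rest(i)[0] /
                max(sum(cm.one_vs_rest(i)[:3]), 1) for i in range(4)]
        assert ious[0] < 1.0 and all(v == 0.0 for v in ious[1:])

    def test_absent_classes_excluded_from_mean(self):
        # only classes 0 and 1 occur; classes 2, 3 must not dilute the mean
        cm = confusion(np.array([0, 1]), np.array([0, 1]), 4)
        assert miou(cm) == 1.0

    def test_all_empty_is_undefined(self):
        with pytest.raises(ValueError):
            miou(ConfusionMatrix(np.zeros((4, 4), dtype=int)))

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_pixel_set_brute_force(self, seed):
        r = np.random.default_rng(seed)
        truth = r.integers(0, 4, size=(12, 12))
        pred = r.integers(0, 4, size=(12, 12))
        ious = []
        for k in range(4):
            a, b = set(zip(*np.nonzero(truth == k))), set(zip(*np.nonzero(pred == k)))
            if a | b:
                ious.append(len(a & b) / len(a | b))
        assert miou(confusion(pred, truth, 4)) == pytest.approx(np.mean(ious))


class TestPrecisionRecallAccuracy:
    def test_perfect_prediction(self, rng):
        truth = rng.integers(0, 4, size=(10, 10))
        cm = confusion(truth, truth, 4)
        for k in np.unique(truth):
            assert precision_recall_accuracy(cm, int(k)) == (1.0, 1.0, 1.0)

    def test_hand_example_class_one(self):
        cm = confusion(np.array([0, 1, 1, 1]), np.array([0, 0, 1, 1]), 2)
        pre, rec, acc = precision_recall_accuracy(cm, 1)
        assert (pre, rec, acc) == (pytest.approx(2 / 3), 1.0, pytest.approx(3 / 4))

    def test_vacuous_class_flagged_undefined(self):
        cm = confusion(np.array([0, 1]), np.array([0, 1]), 4)
        pre, rec, acc = precision_recall_accuracy(cm, 3)
        assert np.isnan(pre) and np.isnan(rec) and acc == 1.0

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_metric_bounds(self, seed):
        r = np.random.default_rng(seed)
        cm = confusion(r.integers(0, 4, size=200), r.integers(0, 4, size=200), 4)
        assert 0.0 <= miou(cm) <= 1.0
        for k in range(4):
            for v in precision_recall_accuracy(cm, k):
                assert np.isnan(v) or 0.0 <= v <= 1.0


class TestLoss:
    def test_confident_correct_logits_approach_minimum(self):
        truth = np.array([[[0, 1], [2, 3]]])
        logits = np.full((1, 4, 2, 2), -50.0, dtype=np.float32)
        for i in range(2):
            for j in range(2):
                logits[0, truth[0, i, j], i, j] = 50.0
        loss = segmentation_loss(Tensor(logits), truth, eps=1.0).item()
        assert loss < 0.01  # CE ~ 0, Dice -> eps-level minimum

    def test_uniform_logits_cross_entropy_is_log2(self):
        truth = np.array([[[0, 1]]])
        logits = np.zeros((1, 2, 1, 2), dtype=np.float32)
        # uniform two-class logits: CE = ln 2; balanced soft Dice = 0.5 per
        # class (Dice loss term = 1 - mean dice with eps correction)
        loss = segmentation_loss(Tensor(logits), truth, eps=0.0).item()
        assert loss == pytest.approx(np.log(2) + 0.5, abs=1e-5)

    def test_gradient_matches_finite_differences(self, rng):
        truth = rng.integers(0, 3, size=(1, 2, 2))
        logits = Tensor(rng.normal(size=(1, 3, 2, 2)), requires_grad=True)
        segmentation_loss(logits, truth).backward()
        ng = numeric_gradient(
            lambda: segmentation_loss(Tensor(logits.data), truth).item(),
            logits.data, eps=1e-5)
        assert np.abs(ng - logits.grad).max() < 1e-4


class TestAugment:
    def _sample(self, rng, size=24):
        img = rng.integers(0, 255, size=(size, size, 3), dtype=np.uint8)
        mask = rng.integers(0, 4, size=(size, size)).astype(np.uint8)
        return ImageSample(image=img, mask=mask, id="a")

    def test_flip_twice_is_identity(self, rng):
        s = self._sample(rng)
        flipped = ImageSample(image=s.image[:, ::-1].copy(),
                              mask=s.mask[:, ::-1].copy(), id="f")
        back = ImageSample(image=flipped.image[:, ::-1].copy(),
                           mask=flipped.mask[:, ::-1].copy(), id="b")
        np.testing.assert_array_equal(back.image, s.image)
        np.testing.assert_array_equal(back.mask, s.mask)

    def test_padding_uses_gray_for_image_background_for_mask(self, rng):
        # an all-shoot input makes the padded region identifiable: it is
        # exactly the background-labelled area of the output
        img = rng.integers(0, 255, size=(16, 16, 3), dtype=np.uint8)
        s = ImageSample(image=img, mask=np.ones((16, 16), dtype=np.uint8), id="p")
        cfg = AugmentConfig(enable_scale=False, enable_flip=False,
                            enable_hsv=False, enable_rotate=False,
                            crop_size=(32, 32))
        out = augment(s, cfg, np.random.default_rng(0))
        assert out.mask.shape == (32, 32)
        pad_region = out.mask == 0
        assert pad_region.sum() == 32 * 32 - 16 * 16
        assert (out.image[pad_region] == 128).all()

    def test_rotation_preserves_class_histogram(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig(enable_scale=False, enable_flip=False,
                            enable_hsv=False, enable_crop=False,
                            rotations=(90, 180, 270))
        for seed in range(6):
            out = augment(s, cfg, np.random.default_rng(seed))
            np.testing.assert_array_equal(np.bincount(out.mask.ravel(), minlength=4),
                                          np.bincount(s.mask.ravel(), minlength=4))

    def test_never_introduces_labels_outside_scheme(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig()
        for seed in range(8):
            out = augment(s, cfg, np.random.default_rng(seed))
            assert set(np.unique(out.mask)) <= {0, 1, 2, 3}
            assert out.image.shape[:2] == out.mask.shape

    def test_deterministic_under_seeded_rng(self, rng):
        s = self._sample(rng)
        a = augment(s, AugmentConfig(), np.random.default_rng(7))
        b = augment(s, AugmentConfig(), np.random.default_rng(7))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)


class TestTrainingProtocol:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_init=0.001, lr_end=0.01)
        with pytest.raises(ValueError):
            TrainConfig(patience=600, max_epochs=500)

    def test_early_stop_fires_at_patience_after_plateau(self):
        # loss decreasing for 5 epochs then flat: stop at epoch 5 + patience
        trace = [1.0, 0.9, 0.8, 0.7, 0.6] + [0.6] * 100
        assert early_stop_epoch(trace, patience=20) == 25

    def test_early_stop_never_before_patience_while_improving(self):
        trace = list(np.linspace(1.0, 0.1, 50))
        assert early_stop_epoch(trace, patience=20) == 50  # never triggers

    def test_stopper_tracks_best_epoch(self):
        s = EarlyStopper(patience=3)
        for e, v in enumerate([1.0, 0.5, 0.7, 0.4, 0.6, 0.6, 0.6], start=1):
            s.update(v, e)
        assert s.best_epoch == 4
        assert s.should_stop
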