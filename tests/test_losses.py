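"""Loss function values, identities and monotonicity properties."""

import numpy as np
import pytest

from lesionseg import evaluate, losses
from lesionseg.losses import LossConfig


def random_pair(rng, shape=(10, 10)):
    x = (rng.random(shape) > 0.5).astype(np.float32)
    y = rng.random(shape).astype(np.float32)
    return x, y


class TestBce:
    def test_perfect_prediction_tiny(self, rng):
        x = (rng.random((8, 8)) > 0.5).astype(np.float32)
        y = np.clip(x, 1e-7, 1 - 1e-7)
        assert losses.bce_loss(x, y) <= 1e-6

    def test_half_probability_is_ln2(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]], dtype=np.float32)
        y = np.full_like(x, 0.5)
        assert losses.bce_loss(x, y) == pytest.approx(np.log(2), rel=1e-5)

    def test_hand_arithmetic_example(self):
        x = np.array([1.0, 0.0], dtype=np.float32)
        y = np.array([0.8, 0.4], dtype=np.float32)
        expected = (-np.log(0.8) - np.log(0.6)) / 2
        assert losses.bce_loss(x, y) == pytest.approx(expected, abs=1e-5)
        assert expected == pytest.approx(0.36698, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            losses.bce_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDice:
    def test_canonical_perfect_is_zero(self, rng):
        x = (rng.random((12, 12)) > 0.4).astype(np.float32)
        assert losses.dice_loss(x, x) == pytest.approx(0.0, abs=1e-7)

    def test_printed_form_perfect_residual(self, rng):
        """The exponent-free printed form retains s/(2s+1) at X == Y."""
        x = (rng.random((12, 12)) > 0.4).astype(np.float32)
        s = float(x.sum())
        cfg = LossConfig(dice_form="as_printed")
        assert losses.dice_loss(x, x, cfg) == pytest.approx(
            s / (2 * s + 1), rel=1e-5)

    def test_hard_prediction_matches_confusion_dice(self):
        """TP=6, FP=2, FN=2 -> dice 0.75, loss 0.25 (vanishing smoothing)."""
        x = np.zeros(16, dtype=np.float32)
        x[:8] = 1  # 8 lesion pixels
        y = np.zeros(16, dtype=np.float32)
        y[:6] = 1   # 6 hits
        y[8:10] = 1  # 2 false alarms
        cfg = LossConfig(smooth=1e-7)
        m = evaluate.metrics(evaluate.confusion(
            y.astype(np.uint8), x.astype(np.uint8)))
        assert m.dice == pytest.approx(0.75)
        assert losses.dice_loss(x, y, cfg) == pytest.approx(0.25, abs=1e-5)


class TestBceDiceCombiner:
    def test_weights(self):
        assert losses.bce_dice_combine(1.0, 0.0) == pytest.approx(0.2)
        assert losses.bce_dice_combine(0.0, 1.0) == pytest.approx(0.8)

    def test_convex_combination_fixed_point(self):
        for a in (0.0, 0.3, 1.7):
            assert losses.bce_dice_combine(a, a) == pytest.approx(a)

    def test_bounded_by_components(self, rng):
        x, y = random_pair(rng)
        b = losses.bce_loss(x, y)
        d = losses.dice_loss(x, y)
        c = losses.bce_dice_loss(x, y)
        assert min(b, d) - 1e-9 <= c <= max(b, d) + 1e-9


class TestFocal:
    def test_closed_form_half(self):
        x = np.array([1.0, 0.0], dtype=np.float32)
        y = np.full_like(x, 0.5)
        cfg = LossConfig(gamma=1.0)
        assert losses.focal_loss(x, y, cfg) == pytest.approx(
            0.5 * np.log(2), rel=1e-5)

    def test_confident_correct_vanishes(self):
        x = np.array([1.0, 0.0], dtype=np.float32)
        y = np.array([1.0 - 1e-7, 1e-7], dtype=np.float32)
        assert losses.focal_loss(x, y) < 1e-6

    def test_printed_form_is_gamma_weighted_bce(self, rng):
        """-γ(1-p)·log p == γ · mean((1-p) · per-pixel BCE)."""
        x, y = random_pair(rng)
        cfg = LossConfig(gamma=0.75)
        yc = np.clip(y, 1e-7, 1 - 1e-7)
        p = x * yc + (1 - x) * (1 - yc)
        oracle = cfg.gamma * np.mean((1 - p) * (-np.log(p)))
        assert losses.focal_loss(x, y, cfg) == pytest.approx(oracle, rel=1e-4)

    def test_canonical_form_exponentiates(self, rng):
        x, y = random_pair(rng)
        cfg = LossConfig(gamma=2.0, focal_form="canonical")
        yc = np.clip(y, 1e-7, 1 - 1e-7)
        p = x * yc + (1 - x) * (1 - yc)
        oracle = np.mean((1 - p) ** 2 * (-np.log(p)))
        assert losses.focal_loss(x, y, cfg) == pytest.approx(oracle, rel=1e-4)


class TestTverskyFamily:
    def test_beta_half_equals_canonical_dice_double_smooth(self, rng):
        """TI at β=1/2 is the Dice ratio: TL(s) == canonical DL(2s)."""
        for _ in range(20):
            x, y = random_pair(rng)
            tl = losses.tversky_loss(x, y, LossConfig(beta=0.5, smooth=1.0))
            dl = losses.dice_loss(x, y, LossConfig(smooth=2.0))
            assert tl == pytest.approx(dl, rel=1e-4)

    def test_perfect_binary_prediction(self, rng):
        x = (rng.random((10, 10)) > 0.5).astype(np.float32)
        # FP = FN = 0: the smoothed index is (s+ΣXY)/(s+ΣXY) = 1, loss 0
        assert losses.tversky_loss(x, x) == pytest.approx(0.0, abs=1e-6)

    def test_beta_one_penalizes_false_positives(self):
        x = np.zeros(9, dtype=np.float32)
        x[:3] = 1
        y = np.full(9, 0.2, dtype=np.float32)
        cfg = LossConfig(beta=1.0)
        base = losses.tversky_loss(x, y, cfg)
        y_fp = y.copy()
        y_fp[5] = 0.8  # raise a background pixel
        assert losses.tversky_loss(x, y_fp, cfg) > base
        y_tp = y.copy()
        y_tp[0] = 0.8  # raise a lesion pixel
        assert losses.tversky_loss(x, y_tp, cfg) < base

    def test_focal_tversky_printed_equals_tversky(self, rng):
        for _ in range(10):
            x, y = random_pair(rng)
            cfg = LossConfig(beta=0.5, smooth=1.0)
            assert losses.focal_tversky_loss(x, y, cfg) == pytest.approx(
                losses.tversky_loss(x, y, cfg), rel=1e-5)

    def test_focal_tversky_exponent_mode(self, rng):
        x, y = random_pair(rng)
        cfg = LossConfig(gamma=0.75, ftl_exponent=True)
        tl = losses.tversky_loss(x, y, cfg)
        assert losses.focal_tversky_loss(x, y, cfg) == pytest.approx(
            tl ** (1 / 0.75), rel=1e-4)


ALL_LOSSES = ["bce", "dice", "bce_dice", "focal", "tversky", "focal_tversky"]


@pytest.mark.parametrize("name", ALL_LOSSES)
def test_nonnegative_and_finite_on_random_pairs(name, rng):
    fn = losses.get_loss(LossConfig(name=name))
    for _ in range(200):
        x, y = random_pair(rng, shape=(6, 6))
        v = fn(x, np.clip(y, 1e-6, 1 - 1e-6))
        assert np.isfinite(v) and v >= -1e-9


@pytest.mark.parametrize("name", ALL_LOSSES)
def test_decreases_as_prediction_approaches_truth(name, rng):
    """Moving one pixel's probability toward its label lowers the loss."""
    fn = losses.get_loss(LossConfig(name=name))
    x, y = random_pair(rng, shape=(5, 5))
    y = np.clip(y, 0.05, 0.95)
    for _ in range(10):
        i, j = rng.integers(0, 5, size=2)
        y2 = y.copy()
        target = x[i, j]
        y2[i, j] = y[i, j] + 0.04 * (1 if target == 1 else -1)
        assert fn(x, y2) < fn(x, y) + 1e-9


def test_cross_module_dice_jaccard_identity(rng):
    """On hard predictions, 1 - dice_loss equals 2J/(1+J) from confusion."""
    for _ in range(20):
        x = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        y = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        m = evaluate.metrics(evaluate.confusion(y, x))
        dl = losses.dice_loss(x.astype(np.float32), y.astype(np.float32),
                              LossConfig(smooth=1e-9))
        assert 1 - dl == pytest.approx(2 * m.jaccard / (1 + m.jaccard),
                                       abs=1e-5)


def test_invalid_configs_rejected():
    for bad in (dict(name="iou"), dict(gamma=-1), dict(beta=2.0),
                dict(w_bce=0.3, w_dice=0.8), dict(smooth=0.0)):
        with pytest.raises(ValueError):
            LossConfig(**bad).validate()
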