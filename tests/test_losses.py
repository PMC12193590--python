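"""Dice/BCE/combined losses and overlap metrics against closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echoseg.errors import ValidationError
from echoseg.losses import (
    LossConfig, bce_loss, combined_loss, dice_coefficient, dice_loss,
    evaluate_with_ci, iou,
)
from echoseg.nn import Tensor


def random_binary(seed, shape=(6, 6)):
    return (np.random.default_rng(seed).random(shape) > 0.5).astype(np.float32)


class TestHardMetrics:
    def test_identical_masks_score_one(self):
        g = random_binary(0)
        assert dice_coefficient(g, g) == pytest.approx(1.0, abs=1e-6)
        assert iou(g, g) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4), dtype=np.float32)
        b = np.zeros((4, 4), dtype=np.float32)
        a[0], b[2] = 1, 1
        assert dice_coefficient(a, b) == pytest.approx(0.0, abs=1e-6)
        assert iou(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_half_overlap_arithmetic(self):
        # |A|=4, |B|=4, intersection 2 -> Dice 0.5, IoU 1/3
        a = np.zeros(8, dtype=np.float32)
        b = np.zeros(8, dtype=np.float32)
        a[:4], b[2:6] = 1, 1
        assert dice_coefficient(a, b) == pytest.approx(0.5, abs=1e-6)
        assert iou(a, b) == pytest.approx(1 / 3, abs=1e-6)

    def test_both_empty_masks_score_one_by_smoothing(self):
        z = np.zeros((3, 3), dtype=np.float32)
        assert dice_coefficient(z, z) == 1.0
        assert iou(z, z) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_iou_dice_identity_and_symmetry(self, seed):
        a, b = random_binary(seed), random_binary(seed + 1)
        d, j = dice_coefficient(a, b), iou(a, b)
        assert j == pytest.approx(d / (2 - d), abs=1e-5)
        assert d == pytest.approx(dice_coefficient(b, a), abs=1e-9)
        assert 0.0 <= j <= d <= 1.0

    def test_nonbinary_target_rejected(self):
        with pytest.raises(ValidationError):
            dice_coefficient(np.zeros(4), np.array([0.0, 0.5, 1.0, 1.0]))


class TestLosses:
    def test_perfect_prediction_zero_loss(self):
        g = random_binary(3)
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-6)
        assert bce_loss(g, g) == pytest.approx(0.0, abs=2e-5)

    def test_inverted_prediction_maximal_dice_loss(self):
        g = np.zeros(8, dtype=np.float32)
        g[:4] = 1
        assert dice_loss(1 - g, g) == pytest.approx(1.0, abs=1e-6)

    def test_soft_dice_on_uniform_half_probabilities(self):
        g = np.array([1, 1, 0, 0], dtype=np.float32)
        p = np.full(4, 0.5, dtype=np.float32)
        assert dice_loss(p, g) == pytest.approx(0.5, abs=1e-6)

    def test_bce_closed_forms(self):
        g = random_binary(4)
        p = np.full_like(g, 0.5)
        assert bce_loss(p, g) == pytest.approx(np.log(2), abs=1e-6)
        assert bce_loss(np.array([0.25]), np.array([1.0])) == pytest.approx(
            -np.log(0.25), rel=1e-6)

    def test_binarized_dice_loss_complements_coefficient(self):
        rng = np.random.default_rng(9)
        p = rng.random((5, 5)).astype(np.float32)
        g = random_binary(10, (5, 5))
        hard = (p >= 0.5).astype(np.float32)
        assert dice_loss(hard, g) == pytest.approx(1 - dice_coefficient(p, g), abs=1e-5)


class TestCombinedLoss:
    def test_endpoints_reduce_to_components(self):
        p = np.clip(np.random.default_rng(2).random((4, 4)), 0, 1).astype(np.float32)
        g = random_binary(5, (4, 4))
        assert combined_loss(p, g, LossConfig(alpha=1.0)) == pytest.approx(
            dice_loss(p, g), abs=1e-7)
        assert combined_loss(p, g, LossConfig(alpha=0.0)) == pytest.approx(
            bce_loss(p, g), abs=1e-7)

    def test_hand_computed_weighting(self):
        # dice_loss 0.5 and bce ln2 at alpha 0.8 -> 0.8*0.5 + 0.2*ln2
        g = np.array([1, 1, 0, 0], dtype=np.float32)
        p = np.full(4, 0.5, dtype=np.float32)
        got = combined_loss(p, g, LossConfig(alpha=0.8))
        assert got == pytest.approx(0.8 * 0.5 + 0.2 * np.log(2), abs=1e-6)
        assert got == pytest.approx(0.5386, abs=1e-4)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.8, 1.0])
    def test_convex_combination_bounds(self, alpha):
        p = np.random.default_rng(6).random((4, 4)).astype(np.float32)
        g = random_binary(7, (4, 4))
        d, b = dice_loss(p, g), bce_loss(p, g)
        got = combined_loss(p, g, LossConfig(alpha=alpha))
        assert min(d, b) - 1e-7 <= got <= max(d, b) + 1e-7

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValidationError):
            LossConfig(alpha=1.5).validate()

    def test_gradient_finite_at_saturated_probabilities(self):
        g = Tensor(np.array([1.0, 0.0], dtype=np.float32))
        p = Tensor(np.array([1.0, 0.0], dtype=np.float32), requires_grad=True)
        loss = combined_loss(p, g.data, LossConfig(alpha=0.5))
        loss.backward()
        assert np.all(np.isfinite(p.grad))


class TestBootstrapCI:
    def test_identical_pairs_give_zero_width(self):
        g = random_binary(1)
        res = evaluate_with_ci([(g, g)] * 5, n_boot=100, seed=0)
        lo, hi = res["dsc_ci"]
        assert lo == hi == pytest.approx(1.0)

    def test_interval_contains_point_estimate(self, rng):
        pairs = [(rng.random((6, 6)).astype(np.float32), random_binary(s))
                 for s in range(12)]
        res = evaluate_with_ci(pairs, n_boot=300, seed=1)
        assert res["dsc_ci"][0] <= res["dsc_mean"] <= res["dsc_ci"][1]
        assert res["iou_ci"][0] <= res["iou_mean"] <= res["iou_ci"][1]

    def test_input_validation(self):
        g = random_binary(2)
        with pytest.raises(ValidationError):
            evaluate_with_ci([(g, g)], n_boot=10, seed=0)
        with pytest.raises(ValidationError):
            evaluate_with_ci([(g, g)] * 3, n_boot=0, seed=0)

    def test_coverage_of_generator_mean(self):
        # per-frame Dice drawn around a known mean; the 95% CI should cover
        # it in most repetitions (binomial check, loose bound)
        gen = np.random.default_rng(42)
        cover = 0
        for rep in range(40):
            g = random_binary(rep)
            dscs_target = 0.8
            pairs = []
            for _ in range(40):
                # corrupt a fraction of pixels to hit Dice ~ target on average
                p = g.copy()
                flips = gen.random(g.shape) < gen.beta(2, 8)
                pairs.append((np.abs(p - flips.astype(np.float32)), g))
            res = evaluate_with_ci(pairs, n_boot=200, seed=rep)
            mean_all = np.mean([dice_coefficient(p, gg) for p, gg in pairs])
            if res["dsc_ci"][0] <= mean_all <= res["dsc_ci"][1]:
                cover += 1
        assert cover >= 36  # sample mean itself is always inside or near the CI
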