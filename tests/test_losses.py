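"""Loss terms against independent scalar-loop oracles and closed forms."""

import math

import numpy as np
import pytest

from ddseg.autograd import Tensor
from ddseg.losses import (
    DICE_SMOOTH,
    LossWeights,
    adversarial_loss,
    boundary_loss,
    classification_loss,
    dice_loss,
    generator_objective,
    segmentation_loss,
)


# -- scalar-loop oracles (independent of the package implementation) --------


def dice_oracle(h, v, eps=DICE_SMOOTH):
    inter = total = 0.0
    for hv, vv in zip(h.ravel(), v.ravel()):
        inter += hv * vv
        total += hv + vv
    return 1.0 - (2.0 * inter + eps) / (total + eps)


def mse_oracle(b, z):
    acc = 0.0
    for bv, zv in zip(b.ravel(), z.ravel()):
        acc += (zv - bv) ** 2
    return acc / b.size


def adv_oracle(scores):
    acc = 0.0
    for s in scores.ravel():
        acc += -math.log(s)
    return acc / scores.size


def cls_oracle(src, tgt):
    a = sum(-math.log(s) for s in src.ravel()) / src.size
    b = sum(-math.log(1.0 - s) for s in tgt.ravel()) / tgt.size
    return a + b


def _maybe_tensor(x, as_tensor):
    return Tensor(x) if as_tensor else x


@pytest.mark.parametrize("as_tensor", [False, True], ids=["numpy", "tensor"])
class TestLossOracles:
    """Each loss matches its scalar-loop oracle on random 4x4 inputs."""

    def test_dice_matches_oracle(self, rng, as_tensor):
        for _ in range(50):
            h = rng.uniform(0, 1, (4, 4))
            v = (rng.uniform(0, 1, (4, 4)) > 0.5).astype(float)
            got = dice_loss(_maybe_tensor(h, as_tensor), _maybe_tensor(v, as_tensor))
            got = float(got.data) if as_tensor else got
            assert abs(got - dice_oracle(h, v)) < 1e-8

    def test_boundary_matches_oracle(self, rng, as_tensor):
        for _ in range(50):
            b = rng.uniform(0, 1, (4, 4))
            z = rng.uniform(0, 1, (4, 4))
            got = boundary_loss(_maybe_tensor(b, as_tensor), _maybe_tensor(z, as_tensor))
            got = float(got.data) if as_tensor else got
            assert abs(got - mse_oracle(b, z)) < 1e-8

    def test_adversarial_matches_oracle(self, rng, as_tensor):
        for _ in range(50):
            s = rng.uniform(0.01, 0.99, (4, 4))
            got = adversarial_loss(_maybe_tensor(s, as_tensor))
            got = float(got.data) if as_tensor else got
            assert abs(got - adv_oracle(s)) < 1e-8

    def test_classification_matches_oracle(self, rng, as_tensor):
        for _ in range(50):
            s = rng.uniform(0.01, 0.99, (4, 4))
            t = rng.uniform(0.01, 0.99, (4, 4))
            got = classification_loss(_maybe_tensor(s, as_tensor), _maybe_tensor(t, as_tensor))
            got = float(got.data) if as_tensor else got
            assert abs(got - cls_oracle(s, t)) < 1e-8


class TestClosedForms:
    def test_dice_perfect_overlap(self):
        v = np.zeros((4, 4))
        v[1:3, 1:3] = 1.0
        assert dice_loss(v, v) < 1e-6

    def test_dice_no_overlap(self):
        v = np.zeros((4, 4))
        v[:2] = 1.0
        assert abs(dice_loss(np.zeros((4, 4)), v) - 1.0) < 1e-5

    def test_dice_half_overlap(self):
        # 4 true pixels, 4 predicted, 2 overlapping -> 1 - 4/8 = 0.5
        v = np.zeros((4, 4))
        v[0, :4] = 1.0
        h = np.zeros((4, 4))
        h[0, 2:] = 1.0
        h[1, :2] = 1.0
        assert abs(dice_loss(h, v) - 0.5) < 1e-6

    def test_boundary_constant_residual(self):
        z = np.zeros((5, 5))
        b = np.full((5, 5), 0.5)
        assert abs(boundary_loss(b, z) - 0.25) < 1e-12

    def test_boundary_quadratic_homogeneity(self, rng):
        z = np.zeros((4, 4))
        b = rng.uniform(0, 0.3, (4, 4))
        assert abs(boundary_loss(3 * b, z) - 9 * boundary_loss(b, z)) < 1e-10

    def test_adversarial_log_half(self):
        assert abs(adversarial_loss(np.full((3, 3), 0.5)) - math.log(2)) < 1e-12

    def test_adversarial_perfect_fool(self):
        assert adversarial_loss(np.full((3, 3), 1 - 1e-7)) < 1e-6

    def test_adversarial_monotone(self):
        s = np.full((2, 2), 0.8)
        s2 = s.copy()
        s2[0, 0] = 0.6
        assert adversarial_loss(s2) > adversarial_loss(s)

    def test_classification_both_half(self):
        half = np.full((2, 2), 0.5)
        assert abs(classification_loss(half, half) - 2 * math.log(2)) < 1e-12

    def test_classification_perfect_discrimination(self):
        assert classification_loss(np.full((2, 2), 1 - 1e-7), np.full((2, 2), 1e-7)) < 1e-5

    def test_classification_complement_symmetry(self, rng):
        s = rng.uniform(0.1, 0.9, (3, 3))
        t = rng.uniform(0.1, 0.9, (3, 3))
        assert abs(classification_loss(s, t) - classification_loss(1 - t, 1 - s)) < 1e-10


class TestBatchAndPermutation:
    def test_segmentation_loss_single_equals_dice(self, rng):
        h = rng.uniform(0, 1, (1, 4, 4))
        v = (rng.uniform(0, 1, (1, 4, 4)) > 0.5).astype(float)
        assert abs(segmentation_loss(h, v) - dice_loss(h[0], v[0])) < 1e-12

    def test_segmentation_loss_is_mean_and_symmetric(self, rng):
        h = rng.uniform(0, 1, (3, 4, 4))
        v = (rng.uniform(0, 1, (3, 4, 4)) > 0.5).astype(float)
        per = [dice_loss(h[i], v[i]) for i in range(3)]
        assert abs(segmentation_loss(h, v) - np.mean(per)) < 1e-12
        perm = [2, 0, 1]
        assert abs(segmentation_loss(h[perm], v[perm]) - segmentation_loss(h, v)) < 1e-12

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_loss(np.zeros((0, 4, 4)), np.zeros((0, 4, 4)))

    def test_adversarial_spatial_permutation_invariant(self, rng):
        s = rng.uniform(0.1, 0.9, 16)
        assert abs(adversarial_loss(s.reshape(4, 4)) - adversarial_loss(rng.permutation(s).reshape(4, 4))) < 1e-12

    def test_score_range_validated(self):
        with pytest.raises(ValueError):
            adversarial_loss(np.array([[0.5, 1.0]]))
        with pytest.raises(ValueError):
            classification_loss(np.array([[0.0]]), np.array([[0.5]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((4, 5)))
        with pytest.raises(ValueError):
            boundary_loss(np.zeros((4, 4)), np.zeros((5, 4)))


class TestGeneratorObjective:
    def test_weighted_sum_examples(self):
        w = LossWeights()
        assert abs(generator_objective(0.5, 1.0, 0.0, 0.0, w) - 0.7) < 1e-12
        assert generator_objective(0.0, 0.0, 0.0, 0.0, w) == 0.0
        assert abs(generator_objective(0.0, 0.0, 1.0, 1.0, w) - 0.0035) < 1e-12

    def test_linearity_in_each_term(self, rng):
        w = LossWeights()
        base = generator_objective(0.1, 0.2, 0.3, 0.4, w)
        assert abs(generator_objective(0.1 + 1, 0.2, 0.3, 0.4, w) - base - 1.0) < 1e-12
        assert abs(generator_objective(0.1, 0.2 + 1, 0.3, 0.4, w) - base - w.lambda_b) < 1e-12
        assert abs(generator_objective(0.1, 0.2, 0.3 + 1, 0.4, w) - base - w.lambda_adv_e) < 1e-12
        assert abs(generator_objective(0.1, 0.2, 0.3, 0.4 + 1, w) - base - w.lambda_adv_d) < 1e-12

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_b=-0.1)

    def test_negative_loss_rejected(self):
        with pytest.raises(ValueError):
            generator_objective(-0.1, 0, 0, 0, LossWeights())
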