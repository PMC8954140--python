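"""Loss values against hand computations and brute-force sums."""

import numpy as np
import pytest

from lgeseg.losses import (EPS, LossWeights, loss_anatomical, loss_ce,
                           loss_class, loss_dice, loss_final, loss_inclusion,
                           loss_soft_iou, onehot_encode, soft_iou_overlap)


def random_pair(rng, shape=(4, 6, 6, 4)):
    """A random probability map (normalised over classes) and a one-hot."""
    u = rng.random(shape) + 1e-3
    u /= u.sum(axis=0, keepdims=True)
    v = onehot_encode(rng.integers(0, shape[0], size=shape[1:]), shape[0])
    return u, v.astype(np.float64)


class TestDice:
    def test_perfect_prediction_all_classes_present(self, rng):
        labels = rng.integers(0, 4, size=(6, 6, 4))
        labels.flat[:4] = [0, 1, 2, 3]  # guarantee presence
        v = onehot_encode(labels, 4).astype(np.float64)
        assert loss_dice(v, v).item() == pytest.approx(-1.0, abs=1e-9)

    def test_zero_mass_on_true_classes(self):
        v = onehot_encode(np.zeros((4, 4, 2), int), 2).astype(np.float64)
        u = np.zeros_like(v)
        u[1] = 1.0  # all mass on the wrong class
        assert loss_dice(u, v).item() == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_and_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        u, v = random_pair(rng, (3, 5, 5, 3))
        val = loss_dice(u, v).item()
        assert -1.0 <= val <= 0.0
        # independent brute-force double loop over classes and voxels
        total = 0.0
        for k in range(3):
            inter = sum(u[k].flat[i] * v[k].flat[i]
                        for i in range(u[k].size))
            sums = sum(u[k].flat[i] for i in range(u[k].size)) \
                + sum(v[k].flat[i] for i in range(v[k].size))
            total += inter / max(sums, EPS)
        assert val == pytest.approx(-2.0 / 3 * total, abs=1e-9)


class TestCrossEntropy:
    def test_perfect_prediction_vanishes(self):
        v = onehot_encode(np.ones((3, 3, 2), int), 3).astype(np.float64)
        u = np.clip(v, 1e-9, 1.0)
        assert loss_ce(u, v).item() == pytest.approx(0.0, abs=1e-6)

    def test_uniform_four_class_is_ln4(self):
        v = onehot_encode(np.zeros((4, 4, 2), int), 4).astype(np.float64)
        u = np.full_like(v, 0.25)
        assert loss_ce(u, v).item() == pytest.approx(np.log(4), abs=1e-9)

    def test_two_voxel_hand_example(self):
        # voxel A: true class 0 with p=0.7; voxel B: true class 1 with p=0.2
        u = np.array([[[[0.7]], [[0.8]]], [[[0.3]], [[0.2]]]])  # (2,2,1,1)
        v = np.array([[[[1.0]], [[0.0]]], [[[0.0]], [[1.0]]]])
        expect = -(np.log(0.7) + np.log(0.2)) / 2
        assert loss_ce(u, v).item() == pytest.approx(expect, abs=1e-9)


class TestAnatomicalComposite:
    def test_is_sum_of_components(self, rng):
        u, v = random_pair(rng)
        assert loss_anatomical(u, v).item() == pytest.approx(
            loss_ce(u, v).item() + loss_dice(u, v).item(), abs=1e-9)

    def test_perfect_prediction_value(self, rng):
        labels = rng.integers(0, 3, size=(6, 6, 2))
        labels.flat[:3] = [0, 1, 2]
        v = onehot_encode(labels, 3).astype(np.float64)
        u = np.clip(v, 1e-12, 1.0)
        assert loss_anatomical(u, v).item() == pytest.approx(-1.0, abs=1e-5)


class TestSoftIoU:
    def test_perfect_one_hot_gives_zero_loss(self, rng):
        labels = rng.integers(0, 4, size=(5, 5, 3))
        labels.flat[:4] = [0, 1, 2, 3]
        v = onehot_encode(labels, 4).astype(np.float64)
        assert loss_soft_iou(v, v).item() == pytest.approx(0.0, abs=1e-6)

    def test_single_voxel_half_half(self):
        p = np.array([0.5, 0.5]).reshape(2, 1, 1, 1)
        pstar = np.array([1.0, 0.0]).reshape(2, 1, 1, 1)
        assert soft_iou_overlap(p, pstar).item() == pytest.approx(0.25,
                                                                  abs=1e-9)
        assert loss_soft_iou(p, pstar).item() == pytest.approx(0.75, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_range_and_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p, pstar = random_pair(rng, (3, 4, 4, 2))
        val = loss_soft_iou(p, pstar).item()
        assert 0.0 <= val <= 1.0
        total = 0.0
        for c in range(3):
            num = float((p[c] * pstar[c]).sum())
            den = float((p[c] + pstar[c] - p[c] * pstar[c]).sum())
            total += num / max(den, EPS)
        assert val == pytest.approx(1.0 - total / 3, abs=1e-9)


class TestInclusion:
    def test_identical_reconstructions_vanish(self, rng):
        r = rng.random((2, 4, 8, 8, 8))
        assert loss_inclusion(r, r).item() == 0.0

    def test_single_entry_of_two(self):
        rp = np.zeros((1, 1, 2, 2, 2))
        rg = rp.copy()
        rp[0, 0, 0, 0, 0] = 2.0
        assert loss_inclusion(rp, rg).item() == pytest.approx(4.0)

    def test_brute_force_on_random_grids(self, rng):
        rp, rg = rng.random((2, 3, 8, 8, 8)), rng.random((2, 3, 8, 8, 8))
        assert loss_inclusion(rp, rg).item() == pytest.approx(
            float(((rp - rg) ** 2).sum()), rel=1e-12)


class TestClassLoss:
    def test_confident_correct_vanishes(self):
        assert loss_class(np.array([20.0, -20.0]), 0).item() < 1e-6

    def test_uniform_scores_ln2(self):
        assert loss_class(np.array([0.0, 0.0]), 1).item() == pytest.approx(
            np.log(2), abs=1e-9)

    def test_hand_computation_one_sample(self):
        s = np.array([1.0, -1.0])
        p1 = np.exp(-1.0) / (np.exp(1.0) + np.exp(-1.0))
        assert loss_class(s, 1).item() == pytest.approx(-np.log(p1), abs=1e-9)


class TestFinalComposite:
    def test_zero_weights_reduce_to_iou_term(self, rng):
        p, pstar = random_pair(rng)
        w = LossWeights(0.0, 0.0)
        val = loss_final(p, pstar, None, None, None, None, w).item()
        assert val == pytest.approx(loss_soft_iou(p, pstar).item(), abs=1e-12)

    def test_perfect_everything_vanishes(self, rng):
        labels = rng.integers(0, 4, size=(4, 4, 2))
        labels.flat[:4] = [0, 1, 2, 3]
        v = onehot_encode(labels, 4).astype(np.float64)
        r = rng.random((1, 4, 4, 4, 2))
        val = loss_final(v, v, r, r, np.array([20.0, -20.0]), 0,
                         LossWeights(0.3, 0.3)).item()
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_linear_in_lambda_ic(self, rng):
        p, pstar = random_pair(rng)
        rp, rg = rng.random((1, 4, 4, 4, 4)), rng.random((1, 4, 4, 4, 4))
        s, lab = np.array([0.3, -0.2]), 1

        def at(lic):
            return loss_final(p, pstar, rp, rg, s, lab,
                              LossWeights(lic, 0.05)).item()

        l0, l1, l2 = at(0.0), at(0.1), at(0.2)
        assert l2 - l1 == pytest.approx(l1 - l0, rel=1e-9)
        assert l1 - l0 == pytest.approx(0.1 * loss_inclusion(rp, rg).item(),
                                        rel=1e-9)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.0)
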