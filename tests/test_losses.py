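"""Oracle and property tests for every loss of the framework."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odcseg.losses import (
    LossWeights,
    adversarial_domain_loss,
    discriminator_bce_loss,
    gram_matrix,
    soft_dice_loss,
    style_gap_loss,
    total_objective,
)
from odcseg.nn import Tensor

LN2 = float(np.log(2.0))


def one_hot_from_labels(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out


class TestSoftDice:
    def test_perfect_prediction_scores_zero(self, rng):
        labels = rng.integers(0, 3, (6, 6))
        y = one_hot_from_labels(labels)
        assert float(soft_dice_loss(y, y)) == pytest.approx(0.0, abs=1e-6)

    def test_total_miss_scores_one(self):
        y = one_hot_from_labels(np.zeros((4, 4), dtype=int))
        p = one_hot_from_labels(np.ones((4, 4), dtype=int))
        assert float(soft_dice_loss(p, y)) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_prediction_on_balanced_classes_scores_half(self):
        # 3x3 toy with exactly 3 pixels per class: each per-channel dice
        # term is 2*(N_c/3) / (N/9*3 + N_c) = 0.5, so the loss is 0.5
        labels = np.arange(9).reshape(3, 3) % 3
        y = one_hot_from_labels(labels)
        p = np.full_like(y, 1.0 / 3.0)
        assert float(soft_dice_loss(p, y)) == pytest.approx(0.5, abs=1e-6)

    def test_spatial_permutation_invariance(self, rng):
        labels = rng.integers(0, 3, (5, 5))
        y = one_hot_from_labels(labels)
        p = rng.random((3, 5, 5)).astype(np.float32)
        p /= p.sum(axis=0)
        perm = rng.permutation(25)
        y_p = y.reshape(3, -1)[:, perm].reshape(3, 5, 5)
        p_p = p.reshape(3, -1)[:, perm].reshape(3, 5, 5)
        assert float(soft_dice_loss(p, y)) == pytest.approx(
            float(soft_dice_loss(p_p, y_p)), rel=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            soft_dice_loss(np.zeros((3, 4, 4)), np.zeros((3, 5, 5)))


class TestGramMatrix:
    def test_all_ones_map(self):
        g = gram_matrix(np.ones((2, 2, 2), dtype=np.float32))
        np.testing.assert_allclose(g.numpy(), [[4.0, 4.0], [4.0, 4.0]])
        assert g.source_shape == (2, 2, 2)

    def test_disjoint_channels_give_zero_off_diagonal(self):
        f = np.zeros((2, 2, 2), dtype=np.float32)
        f[0, 0, :] = 3.0
        f[1, 1, :] = 2.0
        g = gram_matrix(f).numpy()
        assert g[0, 1] == 0.0 and g[1, 0] == 0.0

    def test_single_channel_is_sum_of_squares(self, rng):
        f = rng.random((1, 3, 4)).astype(np.float32)
        g = gram_matrix(f).numpy()
        assert g.shape == (1, 1)
        assert g[0, 0] == pytest.approx(float((f**2).sum()), rel=1e-6)

    def test_matches_bruteforce_double_loop(self, rng):
        f = rng.standard_normal((3, 5, 4)).astype(np.float32)
        g = gram_matrix(f).numpy()
        brute = np.empty((3, 3))
        for r in range(3):
            for c in range(3):
                brute[r, c] = float((f[r] * f[c]).sum())
        np.testing.assert_allclose(g, brute, rtol=1e-6, atol=1e-6)
        # symmetric positive semidefinite
        np.testing.assert_allclose(g, g.T, rtol=1e-6)
        assert np.linalg.eigvalsh(g).min() > -1e-4


class TestStyleGap:
    def test_identical_predictions_have_zero_gap(self, rng):
        p = rng.random((3, 4, 4)).astype(np.float32)
        assert float(style_gap_loss(p, p)) == pytest.approx(0.0, abs=1e-9)

    def test_orthonormal_toy_value(self):
        # two one-hot channels over two pixels: raw Gram(a) = I, Gram(b)
        # = 0, so the gap is sum(I^2) / (HW * C^2) = 2 / (2 * 4) = 0.25
        a = np.zeros((2, 1, 2), dtype=np.float32)
        a[0, 0, 0] = 1.0
        a[1, 0, 1] = 1.0
        b = np.zeros_like(a)
        assert float(style_gap_loss(a, b)) == pytest.approx(0.25, abs=1e-6)

    def test_scaled_toy_reproduces_half(self):
        # scaling the channels so the pixel-normalised Gram difference is
        # the 2x2 identity recovers the closed form (1+0+0+1)/4 = 0.5
        a = np.zeros((2, 1, 2), dtype=np.float32)
        a[0, 0, 0] = 2.0**0.25   # Gram diagonal sqrt(2) = sqrt(HW) * 1
        a[1, 0, 1] = 2.0**0.25
        b = np.zeros_like(a)
        assert float(style_gap_loss(a, b)) == pytest.approx(0.5, abs=1e-6)

    def test_symmetry(self, rng):
        a = rng.random((3, 4, 4)).astype(np.float32)
        b = rng.random((3, 4, 4)).astype(np.float32)
        assert float(style_gap_loss(a, b)) == pytest.approx(
            float(style_gap_loss(b, a)), rel=1e-6)

    def test_channel_mismatch_raises(self):
        with pytest.raises(ValueError, match="channel"):
            style_gap_loss(np.zeros((2, 4, 4)), np.zeros((3, 4, 4)))

    def test_gradient_matches_finite_difference(self, rng):
        a0 = rng.random((3, 4, 4)).astype(np.float32)
        b = rng.random((3, 4, 4)).astype(np.float32)
        t = Tensor(a0.copy(), requires_grad=True)
        style_gap_loss(t, Tensor(b)).backward()
        h = 1e-3
        num = np.zeros_like(a0, dtype=np.float64)
        it = np.nditer(a0, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = a0[idx]
            a0[idx] = orig + h
            fp = float(style_gap_loss(a0, b))
            a0[idx] = orig - h
            fm = float(style_gap_loss(a0, b))
            a0[idx] = orig
            num[idx] = (fp - fm) / (2 * h)
        np.testing.assert_allclose(t.grad, num, atol=1e-4)


class TestDiscriminatorBce:
    def test_chance_logits_give_ln2(self):
        logits = np.zeros((1, 1, 4, 4), dtype=np.float32)
        for z in (0, 1):
            assert float(discriminator_bce_loss(logits, z)) == pytest.approx(
                LN2, abs=1e-6)

    def test_confident_correct_prediction_vanishes(self):
        logits = np.full((1, 1, 2, 2), 20.0, dtype=np.float32)
        assert float(discriminator_bce_loss(logits, 1)) < 1e-6

    def test_sigmoid_symmetry(self, rng):
        logits = rng.standard_normal((1, 1, 3, 3)).astype(np.float32)
        assert float(discriminator_bce_loss(logits, 1)) == pytest.approx(
            float(discriminator_bce_loss(-logits, 0)), rel=1e-5)

    def test_invalid_label_raises(self):
        with pytest.raises(ValueError, match="domain_label"):
            discriminator_bce_loss(np.zeros((1, 1, 2, 2)), 2)


class TestAdversarialDomainLoss:
    def test_fully_fooled_discriminator_gives_zero(self):
        logits = np.full((1, 1, 2, 2), 20.0, dtype=np.float32)
        loss = adversarial_domain_loss(logits, logits, LossWeights())
        assert float(loss) < 1e-6

    def test_chance_logits_give_weighted_ln2(self):
        z = np.zeros((1, 1, 4, 4), dtype=np.float32)
        loss = adversarial_domain_loss(z, z, LossWeights(w_e=0.2, w_o=0.8))
        assert float(loss) == pytest.approx(LN2, abs=1e-6)

    def test_encoding_only_weighting_ignores_output_logits(self, rng):
        enc = rng.standard_normal((1, 1, 2, 2)).astype(np.float32)
        w = LossWeights(w_e=1.0, w_o=0.0)
        a = float(adversarial_domain_loss(enc, np.zeros_like(enc), w))
        b = float(adversarial_domain_loss(enc, 5 + rng.random((1, 1, 2, 2)).astype(np.float32), w))
        assert a == pytest.approx(b, rel=1e-6)

    def test_bad_space_weights_raise(self):
        with pytest.raises(ValueError):
            LossWeights(w_e=0.5, w_o=0.8)


class TestTotalObjective:
    def test_pure_supervision_reduces_to_dice(self):
        w = LossWeights(w_seg=1.0, w_style=0.0, w_domain=0.0)
        total, br = total_objective(0.37, 5.0, 1.0, 1.0, w)
        assert float(total) == pytest.approx(0.37, rel=1e-6)
        assert br.l_total == pytest.approx(br.l_seg, rel=1e-6)

    def test_adversarial_phase_arithmetic(self):
        w = LossWeights(w_seg=0.0, w_style=0.0, w_domain=1.0,
                        w_e=0.2, w_o=0.8)
        total, _ = total_objective(0.0, 0.0, 1.0, 0.5, w)
        assert float(total) == pytest.approx(0.2 * 1.0 + 0.8 * 0.5, rel=1e-6)

    def test_warmup_phase_arithmetic(self):
        total, _ = total_objective(0.4, 2.0, 0.0, 0.0, LossWeights.phase1())
        assert float(total) == pytest.approx(0.4 + 0.05 * 2.0, rel=1e-6)

    def test_breakdown_invariant(self, rng):
        w = LossWeights(w_seg=0.7, w_style=0.1, w_domain=0.3)
        vals = rng.random(4)
        total, br = total_objective(*vals, w)
        expected = (w.w_seg * vals[0] + w.w_style * vals[1]
                    + w.w_domain * (w.w_e * vals[2] + w.w_o * vals[3]))
        assert br.l_total == pytest.approx(expected, rel=1e-5)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_losses_are_nonnegative_and_zero_iff_identical(seed):
    rng = np.random.default_rng(seed)
    p = rng.random((3, 4, 4)).astype(np.float32)
    p /= p.sum(axis=0)
    q = rng.random((3, 4, 4)).astype(np.float32)
    q /= q.sum(axis=0)
    y = one_hot_from_labels(rng.integers(0, 3, (4, 4)))
    assert float(style_gap_loss(p, q)) >= 0.0
    assert float(soft_dice_loss(p, y)) >= 0.0
    assert float(style_gap_loss(p, p)) == pytest.approx(0.0, abs=1e-8)
    assert float(soft_dice_loss(y, y)) == pytest.approx(0.0, abs=1e-6)
    if not np.array_equal(np.argmax(p, 0), np.argmax(y, 0)):
        assert float(soft_dice_loss(p, y)) > 0.0
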