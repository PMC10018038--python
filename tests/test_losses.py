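"""Closed-form identities and invariance properties of the loss suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laaseg.config import LossWeights
from laaseg.losses import (contrastive_loss, cross_entropy_loss, dice_loss,
                           l1_reconstruction_loss, latent_alignment_loss,
                           lsgan_discriminator_loss, lsgan_generator_loss,
                           segmentation_loss, softmax)

TOL = 1e-6


def _onehot_logits(gt: np.ndarray, scale: float = 50.0) -> np.ndarray:
    """Logits that softmax to (numerically) exact one-hot predictions."""
    z = np.zeros((2,) + gt.shape)
    z[1] = scale * (2.0 * gt - 1.0)
    return z


class TestCrossEntropy:
    def test_exact_match_gives_zero(self):
        gt = (np.arange(16).reshape(4, 4) % 3 == 0).astype(int)
        assert cross_entropy_loss(_onehot_logits(gt), gt) == pytest.approx(0.0, abs=TOL)

    def test_uniform_prediction_gives_ln2(self):
        gt = np.zeros((4, 4), dtype=int)
        gt[0, 0] = 1
        logits = np.zeros((2, 4, 4))
        assert cross_entropy_loss(logits, gt) == pytest.approx(np.log(2.0), abs=TOL)

    def test_single_pixel_09(self):
        # p_correct = 0.9 at one pixel -> -ln 0.9
        p = 0.9
        logits = np.array([np.log(1 - p), np.log(p)]).reshape(2, 1, 1)
        gt = np.ones((1, 1), dtype=int)
        assert cross_entropy_loss(logits, gt) == pytest.approx(-np.log(0.9), abs=TOL)

    def test_rejects_illegal_labels(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros((2, 2, 2)), np.full((2, 2), 2))

    def test_gradient_matches_softmax_minus_onehot(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(2, 3, 3))
        gt = (rng.random((3, 3)) > 0.5).astype(int)
        _, grad = cross_entropy_loss(logits, gt, return_grad=True)
        p = softmax(logits[None], axis=1)[0]
        onehot = np.stack([1 - gt, gt])
        np.testing.assert_allclose(grad, (p - onehot) / gt.size, atol=1e-12)


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        g = np.zeros((8, 8))
        g[2:5, 2:5] = 1
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_is_one(self):
        p = np.zeros((8, 8))
        g = np.zeros((8, 8))
        p[0, 0] = 1
        g[7, 7] = 1
        assert dice_loss(p, g) == pytest.approx(1.0, abs=1e-5)

    def test_half_overlap_toy_case(self):
        # two foreground pixels each, one shared -> 1 - 2/4 = 0.5
        p = np.zeros((4, 4))
        g = np.zeros((4, 4))
        p[0, 0] = p[0, 1] = 1
        g[0, 1] = g[0, 2] = 1
        assert dice_loss(p, g, epsilon=1e-12) == pytest.approx(0.5, abs=TOL)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))

    @given(st.integers(0, 2 ** 16 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_for_binary_inputs(self, seed):
        rng = np.random.default_rng(seed)
        p = (rng.random((6, 6)) > 0.6).astype(float)
        g = (rng.random((6, 6)) > 0.6).astype(float)
        assert dice_loss(p, g) == pytest.approx(dice_loss(g, p), abs=1e-12)


class TestSegmentationLoss:
    def test_perfect_prediction_is_zero(self):
        gt = (np.eye(8) > 0).astype(int)
        assert segmentation_loss(_onehot_logits(gt), gt, LossWeights()) == \
            pytest.approx(0.0, abs=1e-4)

    def test_zero_dice_weight_reduces_to_ce(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(2, 5, 5))
        gt = (rng.random((5, 5)) > 0.5).astype(int)
        w = LossWeights(lambda_dice=0.0)
        assert segmentation_loss(logits, gt, w) == \
            pytest.approx(cross_entropy_loss(logits, gt), abs=TOL)

    def test_toy_sum_of_parts(self):
        # uniform logits: CE = ln 2 everywhere; soft-Dice of the constant-0.5
        # map against the toy mask evaluated by the printed formula
        gt = np.zeros((2, 2), dtype=int)
        gt[0, 0] = 1
        logits = np.zeros((2, 2, 2))
        pfg = np.full((2, 2), 0.5)
        expected = np.log(2.0) + dice_loss(pfg, gt.astype(float))
        assert segmentation_loss(logits, gt, LossWeights()) == \
            pytest.approx(expected, abs=TOL)


class TestL1Reconstruction:
    def test_identity_is_zero(self):
        m = (np.random.default_rng(0).random((6, 6)) > 0.5).astype(float)
        assert l1_reconstruction_loss(m, m) == 0.0

    def test_complement_is_one(self):
        m = (np.random.default_rng(0).random((6, 6)) > 0.5).astype(float)
        assert l1_reconstruction_loss(1.0 - m, m) == pytest.approx(1.0, abs=TOL)

    def test_uniform_half_is_half(self):
        m = (np.random.default_rng(0).random((6, 6)) > 0.3).astype(float)
        assert l1_reconstruction_loss(np.full((6, 6), 0.5), m) == \
            pytest.approx(0.5, abs=TOL)


class TestLSGAN:
    def test_discriminator_optimum_is_zero(self):
        assert lsgan_discriminator_loss(np.ones(4), np.zeros(4)) == \
            pytest.approx(0.0, abs=TOL)

    def test_discriminator_half_scores(self):
        s = np.full(8, 0.5)
        assert lsgan_discriminator_loss(s, s) == pytest.approx(0.25, abs=TOL)

    def test_discriminator_worst_case(self):
        assert lsgan_discriminator_loss(np.zeros(3), np.ones(3)) == \
            pytest.approx(1.0, abs=TOL)

    def test_generator_values(self):
        assert lsgan_generator_loss(np.ones(5)) == pytest.approx(0.0, abs=TOL)
        assert lsgan_generator_loss(np.zeros(5)) == pytest.approx(0.5, abs=TOL)
        assert lsgan_generator_loss(np.full(5, -1.0)) == pytest.approx(2.0, abs=TOL)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            lsgan_discriminator_loss(np.ones(0), np.ones(3))
        with pytest.raises(ValueError):
            lsgan_generator_loss(np.ones(0))


class TestContrastive:
    def test_equal_similarities_give_ln_b(self):
        v = np.zeros((8, 16))
        v[:, 0] = 1.0                      # all identical unit vectors
        assert contrastive_loss(v, v, tau=0.1) == pytest.approx(np.log(8.0), abs=TOL)

    def test_saturated_positive_goes_to_zero(self):
        # orthogonal negatives, perfectly aligned positives, tiny temperature
        q = np.eye(4)
        assert contrastive_loss(q, q, tau=0.01) == pytest.approx(0.0, abs=1e-6)

    def test_b2_hand_value(self):
        # q.k+ = 1, q.k- = 0, tau = 0.1 -> -log(e^10 / (e^10 + 1))
        q = np.eye(2)
        k = np.eye(2)
        expected = float(np.log(1.0 + np.exp(-10.0)))
        assert contrastive_loss(q, k, tau=0.1) == pytest.approx(expected, rel=1e-6)

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.ones((1, 4)), np.ones((1, 4)))

    @given(st.integers(0, 2 ** 16 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rotation_invariance(self, seed):
        """Depends only on dot products: any common orthogonal map is a no-op."""
        rng = np.random.default_rng(seed)
        q = rng.normal(size=(4, 6))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        k = rng.normal(size=(4, 6))
        k /= np.linalg.norm(k, axis=1, keepdims=True)
        rot, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        base = contrastive_loss(q, k, tau=0.1)
        assert contrastive_loss(q @ rot, k @ rot, tau=0.1) == \
            pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_finite_for_large_batches(self):
        rng = np.random.default_rng(5)
        q = rng.normal(size=(64, 32))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        k = rng.normal(size=(64, 32))
        k /= np.linalg.norm(k, axis=1, keepdims=True)
        assert np.isfinite(contrastive_loss(q, k, tau=0.1))


class TestJointAlignment:
    def test_zero_terms(self):
        assert latent_alignment_loss(0.0, 0.0, LossWeights()) == 0.0

    def test_cl_weight_zero_reduces_to_gan(self):
        w = LossWeights(lambda_cl=0.0)
        assert latent_alignment_loss(0.37, 9.9, w) == pytest.approx(0.37, abs=TOL)

    def test_weighted_sum(self):
        assert latent_alignment_loss(0.5, 2.0794, LossWeights()) == \
            pytest.approx(2.5794, abs=TOL)


@given(st.integers(0, 2 ** 16 - 1))
@settings(max_examples=20, deadline=None)
def test_all_losses_nonnegative(seed):
    rng = np.random.default_rng(seed)
    logits = rng.normal(size=(2, 4, 4))
    gt = (rng.random((4, 4)) > 0.5).astype(int)
    w = LossWeights()
    q = rng.normal(size=(3, 5))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    k = rng.normal(size=(3, 5))
    k /= np.linalg.norm(k, axis=1, keepdims=True)
    assert cross_entropy_loss(logits, gt) >= 0
    assert 0 <= dice_loss(softmax(logits[None], 1)[0, 1], gt.astype(float)) <= 1
    assert segmentation_loss(logits, gt, w) >= 0
    assert lsgan_discriminator_loss(rng.normal(size=4), rng.normal(size=4)) >= 0
    assert lsgan_generator_loss(rng.normal(size=4)) >= 0
    assert contrastive_loss(q, k, tau=0.1) >= 0
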