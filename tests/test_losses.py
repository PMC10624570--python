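"""Loss components: closed forms, reductions, weighting arithmetic, and
numpy/autodiff agreement."""

import numpy as np
import pytest

import contourprop.autodiff as ad
from contourprop.grid_ops import DisplacementField
from contourprop.losses import (ConfigurationError, LossWeights,
                                bending_energy, ddf_l2_loss,
                                image_similarity_loss, multiscale_dice_loss,
                                soft_dice_loss, total_loss)


def _grid(n=9, h=1.5):
    ax = np.arange(n) * h
    return np.meshgrid(ax, ax, ax, indexing="ij")


class TestBendingEnergy:
    def test_vanishes_on_constant_and_affine_fields(self, rng):
        const = DisplacementField(np.full((3, 8, 8, 8), 2.7), (1.5, 1.5, 1.5))
        assert bending_energy(const) == pytest.approx(0.0, abs=1e-12)
        A = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        X, Y, Z = _grid()
        pts = np.stack([X, Y, Z])
        u = np.einsum("ij,jxyz->ixyz", A, pts) + b.reshape(3, 1, 1, 1)
        e = bending_energy(DisplacementField(u, (1.5, 1.5, 1.5)))
        assert e == pytest.approx(0.0, abs=1e-10 * max(np.abs(u).max(), 1.0))

    def test_quadratic_component_matches_closed_form(self):
        # u_x = x^2 (mm): d2u/dx2 = 2 everywhere -> energy 4, no mixed terms
        X, _, _ = _grid()
        u = np.zeros((3,) + X.shape)
        u[0] = X ** 2
        assert bending_energy(DisplacementField(u, (1.5, 1.5, 1.5))
                              ) == pytest.approx(4.0, rel=1e-12)

    def test_mixed_term_is_doubled(self):
        # u_x = x*y: only d2u/dxdy = 1, counted twice -> energy 2
        X, Y, _ = _grid()
        u = np.zeros((3,) + X.shape)
        u[0] = X * Y
        assert bending_energy(DisplacementField(u, (1.5, 1.5, 1.5))
                              ) == pytest.approx(2.0, rel=1e-12)

    def test_spacing_awareness(self):
        X, _, _ = _grid(h=1.0)
        u = np.zeros((3,) + X.shape)
        u[0] = X ** 2
        assert bending_energy(u, (1.0, 1.0, 1.0)) == pytest.approx(4.0)
        # same voxel values at 2 mm spacing: u = (i*2)^2/... re-evaluate
        X2, _, _ = _grid(h=2.0)
        u2 = np.zeros((3,) + X2.shape)
        u2[0] = X2 ** 2
        assert bending_energy(u2, (2.0, 2.0, 2.0)) == pytest.approx(4.0)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            bending_energy(np.zeros((3, 2, 5, 5)), (1, 1, 1))


class TestDiceLosses:
    def test_perfect_disjoint_and_half_overlap(self):
        a = np.zeros((6, 6, 6))
        a[0:2, 0:2, 0:2] = 1
        assert soft_dice_loss(a, a) == pytest.approx(0.0, abs=1e-4)
        b = np.zeros_like(a)
        b[4:6, 4:6, 4:6] = 1
        assert soft_dice_loss(a, b) == pytest.approx(1.0, abs=1e-4)
        # equal-size cubes sharing half their volume -> Dice 0.5 -> loss 0.5
        c = np.zeros_like(a)
        c[1:3, 0:2, 0:2] = 1
        assert soft_dice_loss(a, c) == pytest.approx(0.5, abs=1e-4)

    def test_multiscale_reduces_to_plain_dice_at_scale_zero(self, rng):
        p = (rng.random((6, 6, 6)) > 0.6).astype(float)
        t = (rng.random((6, 6, 6)) > 0.5).astype(float)
        assert multiscale_dice_loss(p, t, [0.0]) == pytest.approx(
            soft_dice_loss(p, t))
        assert multiscale_dice_loss(t, t, [0.0, 2.0]) == pytest.approx(0.0, abs=1e-3)
        # identical non-binary inputs also score (near) zero at every scale
        q = rng.random((6, 6, 6))
        assert multiscale_dice_loss(q, q, [0.0, 1.0, 3.0]) == pytest.approx(
            0.0, abs=1e-3)

    def test_smoothing_creates_overlap_for_offset_masks(self):
        a = np.zeros((12, 12, 12))
        b = np.zeros((12, 12, 12))
        a[4:6, 4:8, 4:8] = 1
        b[6:8, 4:8, 4:8] = 1  # offset by 2 voxels, no overlap
        plain = multiscale_dice_loss(a, b, [0.0])
        multi = multiscale_dice_loss(a, b, [0.0, 2.0, 4.0])
        assert multi < plain
        with pytest.raises(ValueError):
            multiscale_dice_loss(a, b, [])
        with pytest.raises(ValueError):
            multiscale_dice_loss(a, b, [-1.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)))


class TestImageSimilarity:
    def test_zero_at_perfect_match(self, rng):
        a = rng.normal(size=(5, 5, 5))
        assert image_similarity_loss(a, a, "l2") == pytest.approx(0.0)
        assert image_similarity_loss(a, a, "ncc") == pytest.approx(0.0, abs=1e-12)

    def test_ncc_is_affine_invariant_l2_is_not(self, rng):
        a = rng.normal(size=(5, 5, 5))
        b = 2.0 * a + 3.0
        assert image_similarity_loss(a, b, "ncc") == pytest.approx(0.0, abs=1e-12)
        assert image_similarity_loss(a, b, "l2") > 0.0

    def test_matches_independent_correlation_oracle(self):
        a = np.array([[[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]])
        b = np.array([[[2.0, 1.0], [4.0, 3.0]], [[5.0, 8.0], [6.0, 9.0]]])
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert image_similarity_loss(a, b, "ncc") == pytest.approx(1.0 - r)

    def test_constant_image_degenerates_with_warning(self):
        with pytest.warns(UserWarning):
            val = image_similarity_loss(np.ones((4, 4, 4)),
                                        np.zeros((4, 4, 4)) + 0.5, "ncc")
        assert val == 1.0


class TestDdfL2:
    def test_zero_constant_and_symmetry(self, rng):
        z = np.zeros((3, 5, 5, 5))
        two = np.zeros_like(z)
        two[0] = 2.0
        assert ddf_l2_loss(z, z) == 0.0
        assert ddf_l2_loss(two, z) == pytest.approx(4.0 / 3.0)
        a = rng.normal(size=(3, 5, 5, 5))
        b = rng.normal(size=(3, 5, 5, 5))
        assert ddf_l2_loss(a, b) == pytest.approx(ddf_l2_loss(b, a))
        with pytest.raises(ValueError):
            ddf_l2_loss(a, np.zeros((3, 4, 5, 5)))


class TestTotalLoss:
    W = LossWeights(lambda_ddf=1.0, lambda_ddf_l2=0.0, lambda_ddf_reg=10.0,
                    lambda_seg=100.0, lambda_img=1.0)

    def test_weighted_sum_arithmetic(self):
        comps = {"ddf_reg": 0.01, "seg": 0.02, "img": 0.05}
        assert total_loss(comps, self.W, has_gt_ddf=False) == pytest.approx(2.15)

    def test_l2_term_dropped_without_ground_truth(self):
        w = LossWeights(lambda_ddf=1.0, lambda_ddf_l2=5.0, lambda_ddf_reg=10.0,
                        lambda_seg=100.0, lambda_img=1.0)
        comps = {"ddf_reg": 0.01, "seg": 0.02, "img": 0.05, "ddf_l2": 1.0}
        with_gt = total_loss(comps, w, has_gt_ddf=True)
        without = total_loss(comps, w, has_gt_ddf=False)
        assert with_gt == pytest.approx(2.15 + 5.0)
        assert without == pytest.approx(2.15)

    def test_outer_weight_doubling_doubles_total(self):
        comps = {"ddf_reg": 0.01, "seg": 0.02, "img": 0.05}
        w2 = LossWeights(lambda_ddf=2.0, lambda_ddf_l2=0.0, lambda_ddf_reg=10.0,
                         lambda_seg=200.0, lambda_img=2.0)
        assert total_loss(comps, w2, False) == pytest.approx(
            2 * total_loss(comps, self.W, False))

    def test_all_zero_components_give_zero(self):
        comps = {"ddf_reg": 0.0, "seg": 0.0, "img": 0.0}
        assert total_loss(comps, self.W, False) == 0.0

    def test_missing_component_with_nonzero_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            total_loss({"seg": 0.1, "img": 0.1}, self.W, False)
        with pytest.raises(ConfigurationError):
            LossWeights(lambda_seg=-1.0).validate()


def test_losses_agree_between_numpy_and_autodiff_paths(rng):
    p = rng.random((3, 8, 8, 8))
    t = rng.random((3, 8, 8, 8))
    pairs = [
        (bending_energy(p, (1.5, 1.5, 1.5)),
         bending_energy(ad.Tensor(p, requires_grad=True), (1.5, 1.5, 1.5))),
        (soft_dice_loss(p[0], t[0] > 0.5),
         soft_dice_loss(ad.Tensor(p[0], requires_grad=True),
                        (t[0] > 0.5).astype(float))),
        (multiscale_dice_loss(p[0], (t[0] > 0.5).astype(float), [0, 2]),
         multiscale_dice_loss(ad.Tensor(p[0], requires_grad=True),
                              (t[0] > 0.5).astype(float), [0, 2])),
        (image_similarity_loss(p[0], t[0], "ncc"),
         image_similarity_loss(ad.Tensor(p[0], requires_grad=True), t[0], "ncc")),
        (ddf_l2_loss(p, t), ddf_l2_loss(ad.Tensor(p, requires_grad=True), t)),
    ]
    for plain, tensor in pairs:
        assert tensor.item() == pytest.approx(plain, rel=1e-10)
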