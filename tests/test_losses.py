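import numpy as np
import pytest

from sacseg.imageio_points import UNLABELED
from sacseg.losses import LossWeights, att_loss, cons_loss, seg_loss, total_loss
from sacseg.nn import functional as F
from sacseg.nn.autodiff import Tensor


class TestSegLoss:
    def test_perfect_fit_is_zero(self):
        ones = np.ones((4, 4))
        assert seg_loss(ones, ones, np.ones((4, 4), np.uint8)).item() <= 1e-6

    def test_zero_mask_zero_label_is_zero(self):
        z = np.zeros((4, 4))
        assert seg_loss(np.random.default_rng(0).random((4, 4)), z,
                        np.zeros((4, 4), np.uint8)).item() <= 1e-6

    def test_single_pixel_hand_value(self):
        val = seg_loss(np.array([[0.8]]), np.array([[1.0]]),
                       np.array([[1]], np.uint8)).item()
        assert val == pytest.approx(-np.log(0.8), abs=1e-9)

    def test_unlabeled_code_rejected(self):
        y = np.full((2, 2), UNLABELED, np.uint8)
        with pytest.raises(ValueError):
            seg_loss(np.ones((2, 2)), np.ones((2, 2)), y)


class TestAttLoss:
    def _yv(self):
        y = np.full((2, 2), UNLABELED, np.uint8)
        y[0, 0] = 1
        y[0, 1] = 1
        y[1, 0] = 0
        return y

    def test_confident_map_scores_zero(self):
        f = np.ones((2, 2))
        assert att_loss(f, self._yv(), alpha=0.4).item() == pytest.approx(0.0)

    def test_hand_value_two_pos_one_neg(self):
        f = np.full((2, 2), 0.5)
        assert att_loss(f, self._yv(), alpha=0.4).item() == \
            pytest.approx(0.7, abs=1e-9)

    def test_alpha_scales_only_the_negative_term(self):
        f = np.full((2, 2), 0.5)
        assert att_loss(f, self._yv(), alpha=0.8).item() == \
            pytest.approx(0.9, abs=1e-9)

    def test_unlabeled_pixels_do_not_contribute(self):
        f = np.full((2, 2), 0.5)
        y = self._yv()
        f2 = f.copy()
        f2[1, 1] = 0.123  # the unlabeled pixel
        assert att_loss(f, y).item() == att_loss(f2, y).item()

    def test_empty_sets_error_names_the_set(self):
        y = np.full((2, 2), UNLABELED, np.uint8)
        y[0, 0] = 1
        with pytest.raises(ValueError, match="negative"):
            att_loss(np.ones((2, 2)), y)
        y[:] = UNLABELED
        y[0, 0] = 0
        with pytest.raises(ValueError, match="positive"):
            att_loss(np.ones((2, 2)), y)

    def test_alternative_negative_target(self):
        f = np.full((2, 2), 0.5)
        # with negatives pulled toward 0: 0.5 + 0.4*0.5 is unchanged at 0.5,
        # but a confident-background map now scores 0 on the negative term
        conf = np.ones((2, 2))
        conf[1, 0] = 0.0
        assert att_loss(conf, self._yv(), alpha=0.4,
                        neg_target=0.0).item() == pytest.approx(0.0)


class TestConsLoss:
    def test_identical_channels_score_zero(self):
        f = np.random.default_rng(0).random((1, 1, 3, 3))
        h = np.repeat(f, 4, axis=1)
        assert cons_loss(f, h).item() == pytest.approx(0.0)

    def test_single_pixel_hand_value(self):
        f = np.array([[[[0.8]]]])
        h = np.array([[[[0.5]], [[0.9]]]])
        assert cons_loss(f, h).item() == pytest.approx(0.2, abs=1e-9)

    def test_invariant_to_channel_permutation(self):
        rng = np.random.default_rng(1)
        f = rng.random((1, 1, 4, 4))
        h = rng.random((1, 3, 4, 4))
        assert cons_loss(f, h).item() == \
            pytest.approx(cons_loss(f, h[:, ::-1]).item())


class TestTotalLoss:
    def test_hand_value_with_reference_weights(self):
        w = LossWeights(alpha=0.4, beta=0.8, gamma=1.0, delta=0.4)
        assert total_loss(0.5, 0.7, 0.2, w) == pytest.approx(1.18, abs=1e-9)

    def test_zero_components_give_zero(self):
        assert total_loss(0.0, 0.0, 0.0, LossWeights()) == 0.0

    def test_monotone_in_each_component(self):
        w = LossWeights()
        base = total_loss(0.5, 0.7, 0.2, w)
        assert total_loss(0.6, 0.7, 0.2, w) >= base
        assert total_loss(0.5, 0.8, 0.2, w) >= base
        assert total_loss(0.5, 0.7, 0.3, w) >= base

    def test_non_finite_component_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.inf, 0.0, 0.0, LossWeights())

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)


class TestGradientIsolation:
    def test_detached_attention_mask_blocks_seg_gradient(self):
        """Perturbing the attention map must not change the segmentation
        gradient when the mask is detached inside seg_loss."""
        rng = np.random.default_rng(0)
        pred_data = rng.random((1, 1, 4, 4))
        y = (rng.random((4, 4)) > 0.5).astype(np.uint8)

        def seg_grad(att_values, detach):
            pred = Tensor(pred_data, requires_grad=True)
            f_att = Tensor(att_values, requires_grad=True)
            seg_loss(pred, f_att, y, detach=detach).backward()
            return pred.grad.copy(), f_att.grad

        att_a = np.full((1, 1, 4, 4), 0.9)
        g_pred, g_att = seg_grad(att_a, detach=True)
        assert g_att is None                 # no gradient reaches the mask
        # with detach off, the mask does receive a gradient
        _, g_att_joint = seg_grad(att_a, detach=False)
        assert g_att_joint is not None and np.abs(g_att_joint).max() > 0

    def test_detached_prediction_blocks_cons_gradient(self):
        rng = np.random.default_rng(1)
        f = Tensor(rng.random((1, 1, 3, 3)), requires_grad=True)
        h = Tensor(rng.random((1, 2, 3, 3)), requires_grad=True)
        cons_loss(f, h, detach=True).backward()
        assert f.grad is None
        assert h.grad is not None

    def test_losses_are_nonnegative_and_finite(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pred = rng.random((1, 1, 5, 5))
            att = rng.random((1, 1, 5, 5))
            y = (rng.random((5, 5)) > 0.5).astype(np.uint8)
            yv = rng.choice([0, 1, UNLABELED], size=(5, 5)).astype(np.uint8)
            if not ((yv == 0).any() and (yv == 1).any()):
                continue
            h = rng.random((1, 3, 5, 5))
            vals = [seg_loss(pred, att, y).item(),
                    att_loss(att, yv).item(),
                    cons_loss(pred, h).item()]
            assert all(np.isfinite(v) and v >= 0 for v in vals)
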